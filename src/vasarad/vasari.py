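"""The 23-trait VASARI lexicon: validation and numeric encoding.

VASARI (Visually Accessible Rembrandt Images) is a standardized vocabulary
of qualitative MRI traits scored by radiologists.  This module ships the
trait domain table as an editable JSON resource, validates records against
it, and encodes categories as integers so qualitative scores can enter the
same feature-selection and modeling machinery as radiomics features.

Encoding: every trait maps to a single integer column.  Ordinal traits
(e.g. the necrosis proportion bands) are coded by rank, 1-based, so the code
order matches the clinical order; nominal traits (e.g. tumor location) use
documented 1-based codes in the lexicon's listing order.  The per-trait
mapping is bijective, so records round-trip through encode/decode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .types import FeatureTable

VASARIRecord = dict


def _load_default_lexicon() -> dict:
    text = resources.files("vasarad.data").joinpath("vasari_lexicon.json").read_text()
    return json.loads(text)


@dataclass
class VASARILexicon:
    """Trait domain table plus the integer encoding derived from it."""

    traits: dict[str, dict] = field(default_factory=lambda: _load_default_lexicon()["traits"])

    def __post_init__(self) -> None:
        self.encoding: dict[str, dict[str, int]] = {
            trait: {cat: i + 1 for i, cat in enumerate(spec["categories"])}
            for trait, spec in self.traits.items()
        }
        self.decoding: dict[str, dict[int, str]] = {
            trait: {code: cat for cat, code in mapping.items()}
            for trait, mapping in self.encoding.items()
        }

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def is_ordinal(self, trait: str) -> bool:
        return self.traits[trait]["kind"] == "ordinal"

    def categories(self, trait: str) -> list[str]:
        return list(self.traits[trait]["categories"])

    def validate_record(self, record: VASARIRecord) -> list[str]:
        """Return a list of problems; an empty list means the record is valid."""
        problems = []
        for trait, spec in self.traits.items():
            if trait not in record:
                problems.append(f"missing trait: {trait!r}")
            elif record[trait] not in spec["categories"]:
                problems.append(
                    f"trait {trait!r}: value {record[trait]!r} not in domain "
                    f"{spec['categories']}"
                )
        for key in record:
            if key not in self.traits:
                problems.append(f"unknown trait: {key!r}")
        return problems

    def encode_record(self, record: VASARIRecord) -> dict[str, int]:
        problems = self.validate_record(record)
        if problems:
            raise ValueError("invalid VASARI record: " + "; ".join(problems))
        return {trait: self.encoding[trait][record[trait]] for trait in self.traits}

    def decode_record(self, codes: dict[str, int]) -> VASARIRecord:
        return {trait: self.decoding[trait][int(codes[trait])] for trait in self.traits}

    def encode_records(self, records: dict, labels: dict) -> FeatureTable:
        """Encode {subject_id: record} into a 23-column numeric FeatureTable."""
        rows = {sid: self.encode_record(rec) for sid, rec in records.items()}
        data = pd.DataFrame.from_dict(rows, orient="index")[self.trait_names].astype(float)
        return FeatureTable(data, pd.Series(labels).loc[data.index])


DEFAULT_LEXICON = VASARILexicon()
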