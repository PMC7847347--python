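"""File-format plumbing: NIfTI volumes, manifests, feature tables.

Volumes and masks are written as compressed NIfTI with the voxel spacing on
the affine diagonal; tabular artifacts are plain CSV/JSON so every pipeline
stage remains inspectable with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import FeatureTable, MaskedVolume


def write_volume(volume: MaskedVolume, image_path, mask_path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), affine), str(mask_path))


def read_volume(image_path, mask_path) -> MaskedVolume:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskedVolume(
        np.asarray(img.dataobj, dtype=float),
        np.asarray(msk.dataobj) > 0,
        spacing,
    )


def write_cohort(cohort, out_dir) -> pd.DataFrame:
    """Write per-subject NIfTI pairs, VASARI CSV, manifest CSV and config JSON."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    vasari_rows = {}
    for s in cohort.subjects:
        ipath = out / "volumes" / f"{s.id}_adc.nii.gz"
        mpath = out / "volumes" / f"{s.id}_mask.nii.gz"
        write_volume(s.volume, ipath, mpath)
        rows.append(
            {
                "id": s.id, "label": s.label, "age": s.age, "gender": s.gender,
                "image": str(ipath.relative_to(out)), "mask": str(mpath.relative_to(out)),
            }
        )
        vasari_rows[s.id] = s.vasari
    manifest = pd.DataFrame(rows).set_index("id")
    manifest.to_csv(out / "manifest.csv")
    pd.DataFrame.from_dict(vasari_rows, orient="index").rename_axis("id").to_csv(
        out / "vasari.csv"
    )
    cfg = cohort.config
    config_dict = {
        "n_subjects": cfg.n_subjects,
        "mutant_fraction": cfg.mutant_fraction,
        "volume_shape": list(cfg.volume_shape),
        "voxel_spacing": list(cfg.voxel_spacing),
        "tumor_radius_range": list(cfg.tumor_radius_range),
        "seed": cfg.seed,
        "class_effects": vars(cfg.class_effects),
    }
    (out / "config.json").write_text(json.dumps(config_dict, indent=2))
    return manifest


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df["label"] = table.labels
    df.rename_axis("id").to_csv(path)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col="id")
    labels = df.pop("label")
    return FeatureTable(df, labels)


def write_selection(result, path_csv, path_json=None) -> None:
    pd.DataFrame({"feature": result.features, "auc": result.aucs}).to_csv(
        path_csv, index=False
    )
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(
                {
                    "features": result.features,
                    "aucs": result.aucs,
                    "pool": result.pool,
                    "pool_size": result.pool_size,
                    "n_replicates": result.n_replicates,
                    "seed": result.seed,
                },
                indent=2,
            )
        )
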