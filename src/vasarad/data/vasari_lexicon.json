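{
  "_comment": "23-trait VASARI domain table. Category sets for the non-highlighted traits follow the public VASARI guide; edit this file to adapt the lexicon. 'kind' is 'ordinal' (codes follow the listed rank order) or 'nominal' (codes are documented integers in listing order).",
  "version": 1,
  "traits": {
    "tumor location": {"kind": "nominal", "categories": ["frontal", "temporal", "parietal", "occipital", "insular", "brainstem", "cerebellar", "other"]},
    "side of lesion epicenter": {"kind": "nominal", "categories": ["right", "center", "left"]},
    "eloquent brain involvement": {"kind": "nominal", "categories": ["none", "speech motor", "speech receptive", "motor", "vision"]},
    "enhancement quality": {"kind": "ordinal", "categories": ["none", "mild", "marked"]},
    "proportion enhancing": {"kind": "ordinal", "categories": ["0%", "<5%", "6-33%", "34-67%", "68-95%", ">95%"]},
    "proportion non-enhancing": {"kind": "ordinal", "categories": ["0%", "<5%", "6-33%", "34-67%", "68-95%", ">95%"]},
    "proportion of necrosis": {"kind": "ordinal", "categories": ["0%", "<5%", "6-33%", "34-67%", "68-95%", ">95%"]},
    "cysts": {"kind": "nominal", "categories": ["absent", "present"]},
    "focality": {"kind": "nominal", "categories": ["focal", "multifocal", "multicentric", "gliomatosis"]},
    "T1/FLAIR ratio": {"kind": "nominal", "categories": ["expansive", "mixed", "infiltrative"]},
    "thickness of enhancing margin": {"kind": "ordinal", "categories": ["none", "thin", "thick"]},
    "definition of enhancing margin": {"kind": "nominal", "categories": ["not applicable", "well-defined", "poorly-defined"]},
    "definition of non-enhancing margin": {"kind": "nominal", "categories": ["smooth", "irregular"]},
    "proportion of edema": {"kind": "ordinal", "categories": ["0%", "<5%", "6-33%", "34-67%", "68-95%", ">95%"]},
    "edema crosses midline": {"kind": "nominal", "categories": ["absent", "present"]},
    "hemorrhage": {"kind": "nominal", "categories": ["absent", "present"]},
    "diffusion characteristics": {"kind": "nominal", "categories": ["facilitated", "restricted", "mixed"]},
    "pial invasion": {"kind": "nominal", "categories": ["absent", "present"]},
    "ependymal invasion": {"kind": "nominal", "categories": ["absent", "present"]},
    "cortical involvement": {"kind": "nominal", "categories": ["absent", "present"]},
    "deep white matter invasion": {"kind": "nominal", "categories": ["absent", "present"]},
    "non-enhancing tumor crosses midline": {"kind": "nominal", "categories": ["absent", "present"]},
    "satellites": {"kind": "nominal", "categories": ["absent", "present"]}
  }
}
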