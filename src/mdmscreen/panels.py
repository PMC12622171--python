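"""Built-in metabolite panels for the ASD urinary MDM screen.

Two panels are provided, mirroring the two arms of the study design:

* the **semiquantitative** panel — 19 metabolites measured as untargeted
  LC-MS peak intensities (phenylalanine-derived, tryptophan-derived, and
  yeast/other microbial compounds). N-formyl methionine is the single
  low-direction marker: it is depleted, not elevated, in the affected group.
* the **quantitative** panel — 24 analytes (plus two ratio
  pseudo-metabolites) measured against commercial standards, in µmol/mmol
  creatinine after normalization.

Alongside each panel the module records the published per-metabolite
fractions of ASD participants falling outside the TD reference range
(``SEMIQUANT_EXCEEDANCE_TARGETS``), the published group means for the
quantitative analytes (``QUANT_GROUP_MEANS``), and the published
below-LOD fractions (``QUANT_BELOW_LOD``). These printed summary values are
inputs: the synthetic-cohort generator calibrates to them, and the worked
examples recompute derived columns from them.
"""

from __future__ import annotations

from .panel import MetabolitePanel, PanelEntry

# (metabolite_id, display_name, family, direction, fraction of ASD outside TD range)
_SEMIQUANT_ROWS = [
    ("aminopropoxy_dimethylphenol", "4-(2-Aminopropoxy)-3,5-dimethylphenol",
     "phenylalanine", "high", 0.10),
    ("amino_m_cresol", "6-Amino-m-cresol", "phenylalanine", "high", 0.12),
    ("phenylacetylglutamine", "Phenylacetylglutamine", "phenylalanine", "high", 0.32),
    ("p_cresol", "p-Cresol", "phenylalanine", "high", 0.24),
    ("p_cresol_sulfate", "p-Cresol Sulfate", "phenylalanine", "high", 0.32),
    ("phenol_sulfonic_acid", "4-Phenol Sulfonic Acid", "phenylalanine", "high", 0.04),
    ("methyl_3_indole_acetate", "Methyl-3-Indole Acetate", "tryptophan", "high", 0.34),
    ("indole_3_propionic_acid", "3-Indolepropionic Acid", "tryptophan", "high", 0.34),
    ("methyl_tetrahydro_beta_carboline",
     "1-Methyl-1,2,3,4-tetrahydro-beta-carboline-3-carboxylic acid",
     "tryptophan", "high", 0.44),
    ("methyldioxyindole", "3-Methyldioxyindole", "tryptophan", "high", 0.22),
    ("methoxyindole_acetate", "5-Methoxyindole Acetate", "tryptophan", "high", 0.12),
    ("indole_3_acryloyl_glycine", "Indole-3-acryloyl Glycine", "tryptophan", "high", 0.10),
    ("indole_3_acrylic_acid", "trans-3-Indoleacrylic Acid", "tryptophan", "high", 0.22),
    ("indole_4_carbaldehyde", "4-Indolecarbaldehyde", "tryptophan", "high", 0.22),
    ("indole_3_acetonitrile", "3-Indoleacetonitrile", "tryptophan", "high", 0.14),
    ("indole_3_acetaldoxime", "Indole-3-acetaldoxime", "tryptophan", "high", 0.14),
    ("indoxyl_sulfate", "Indoxyl Sulfate", "tryptophan", "high", 0.0),
    ("arabinitol", "Arabinitol", "yeast_other", "high", 0.17),
    ("n_formyl_methionine", "N-Formyl Methionine", "yeast_other", "low", 0.17),
]

#: Published fraction of ASD participants outside the TD reference range for
#: each semiquantitative metabolite; the generator's calibration targets.
SEMIQUANT_EXCEEDANCE_TARGETS: dict[str, float] = {
    mid: frac for mid, _, _, _, frac in _SEMIQUANT_ROWS
}


def builtin_semiquant_panel() -> MetabolitePanel:
    """The 19-metabolite untargeted (peak-intensity) panel."""
    return MetabolitePanel(
        [
            PanelEntry(mid, name, family, direction, lod=None,
                       units="peak intensity")
            for mid, name, family, direction, _ in _SEMIQUANT_ROWS
        ]
    )


# (metabolite_id, display_name, family, mean_asd, mean_td,
#  fraction ASD above TD range, fraction below LOD, is_ratio)
_QUANT_ROWS = [
    ("p_cresol_sulfate", "p-Cresol Sulphate", "phenylalanine", 2564.0, 1072.0, 0.21, 0.00, False),
    ("p_cresol", "p-Cresol", "phenylalanine", 0.44, 0.25, 0.19, 0.00, False),
    ("hydroxybenzoic_acid", "Hydroxybenzoic Acid", "phenylalanine", 4.73, 1.03, 0.17, 0.31, False),
    ("benzoic_acid", "Benzoic Acid", "phenylalanine", 1.26, 0.71, 0.13, 0.08, False),
    ("phenylacetylglutamine", "Phenylacetylglutamine", "phenylalanine", 0.80, 0.44, 0.13, 0.00, False),
    ("phe_tyr_ratio", "Phe/Tyr", "phenylalanine", 1.65, 1.22, 0.10, 0.00, True),
    ("benzoic_hippuric_ratio", "Benzoic/Hippuric", "phenylalanine", 0.02, 0.01, 0.08, 0.03, True),
    ("hippuric_acid", "Hippuric Acid", "phenylalanine", 84.0, 54.0, 0.08, 0.00, False),
    ("dhppa", "DHPPA", "phenylalanine", 0.64, 0.56, 0.04, 0.08, False),
    ("phenylacetic_acid", "Phenylacetic Acid", "phenylalanine", 1.50, 1.17, 0.04, 0.15, False),
    ("phenylpropionic_acid", "Phenyl Propionic Acid", "phenylalanine", 0.01, 0.03, 0.00, 0.76, False),
    ("indole_3_acryloyl_glycine", "Indole-3-acryloyl Glycine", "tryptophan", 7.95, 3.77, 0.17, 0.00, False),
    ("indole_3_propionic_acid", "3-Indolepropionic Acid", "tryptophan", 0.02, 0.01, 0.15, 0.00, False),
    ("indole_4_carbaldehyde", "4-Indolecarbaldehyde", "tryptophan", 0.02, 0.01, 0.13, 0.00, False),
    ("methyldioxyindole", "3-Methyldioxyindole", "tryptophan", 0.004, 0.001, 0.12, 0.70, False),
    ("indoxyl_sulfate", "Indoxyl Sulfate", "tryptophan", 43.0, 16.0, 0.10, 0.00, False),
    ("oxindole_2", "2-Oxindole", "tryptophan", 0.003, 0.0001, 0.08, 0.94, False),
    ("indole_3_acetonitrile", "3-Indoleacetonitrile", "tryptophan", 0.004, 0.002, 0.06, 0.08, False),
    ("methyl_tetrahydro_beta_carboline",
     "1-Methyl-1,2,3,4-tetrahydro-beta-carboline", "tryptophan", 0.022, 0.008, 0.06, 0.00, False),
    ("methoxyindole_5", "5-Methoxyindole", "tryptophan", 0.0001, 0.002, 0.00, 0.95, False),
    ("arabinitol", "Arabinitol", "yeast_other", 37.0, 27.0, 0.10, 0.00, False),
    ("citramalic_acid", "Citramalic Acid", "yeast_other", 0.11, 0.06, 0.04, 0.00, False),
    ("tartaric_acid", "Tartaric Acid", "yeast_other", 0.274, 0.053, 0.02, 0.36, False),
    ("tricarballylic_acid", "Tricarballylic Acid", "yeast_other", 0.845, 0.001, 0.00, 0.30, False),
]

#: Published (mean_ASD, mean_TD) in µmol/mmol creatinine for the quantitative
#: analytes; inputs to the percent-difference worked examples.
QUANT_GROUP_MEANS: dict[str, tuple[float, float]] = {
    mid: (a, t) for mid, _, _, a, t, _, _, _ in _QUANT_ROWS
}

#: Published fraction of ASD participants above the TD range (quantitative arm).
QUANT_EXCEEDANCE_TARGETS: dict[str, float] = {
    mid: above for mid, _, _, _, _, above, _, _ in _QUANT_ROWS
}

#: Published pooled fraction of participants below the limit of detection.
QUANT_BELOW_LOD: dict[str, float] = {
    mid: lod for mid, _, _, _, _, _, lod, _ in _QUANT_ROWS
}


def builtin_quant_panel() -> MetabolitePanel:
    """The 24-analyte targeted panel (two entries are ratio pseudo-metabolites)."""
    return MetabolitePanel(
        [
            PanelEntry(mid, name, family, "high", lod=None,
                       units="ratio" if is_ratio else "umol/L",
                       is_ratio=is_ratio)
            for mid, name, family, _, _, _, _, is_ratio in _QUANT_ROWS
        ]
    )
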