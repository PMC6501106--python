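"""Catalogue of the 47 GC-MS primary metabolites used by the simulator.

The biomarker metabolites (glycine, methionine, threonic acid,
myo-inositol, raffinose, arginine) and mannitol are fixed by the study
system; the remainder of the catalogue is a synthetic stand-in filled
with standard GC-MS-detectable primary metabolites of the three classes
(amino acids, organic acids, carbohydrates/polyols) so that simulated
matrices have realistic names and class structure.
"""

from __future__ import annotations

AMINO_ACIDS = [
    "alanine",
    "arginine",
    "asparagine",
    "aspartic acid",
    "GABA",
    "glutamic acid",
    "glutamine",
    "glycine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "proline",
    "serine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
]

ORGANIC_ACIDS = [
    "ascorbic acid",
    "benzoic acid",
    "citric acid",
    "fumaric acid",
    "glyceric acid",
    "glycolic acid",
    "lactic acid",
    "malic acid",
    "oxalic acid",
    "pyruvic acid",
    "quinic acid",
    "shikimic acid",
    "succinic acid",
    "threonic acid",
]

CARBOHYDRATES = [
    "fructose",
    "galactose",
    "glucose",
    "glycerol",
    "maltose",
    "mannitol",
    "myo-inositol",
    "raffinose",
    "rhamnose",
    "ribose",
    "sucrose",
    "trehalose",
    "xylose",
]

CATALOGUE: list[str] = AMINO_ACIDS + ORGANIC_ACIDS + CARBOHYDRATES

METABOLITE_CLASS: dict[str, str] = {
    **{m: "amino acid" for m in AMINO_ACIDS},
    **{m: "organic acid" for m in ORGANIC_ACIDS},
    **{m: "carbohydrate" for m in CARBOHYDRATES},
}

assert len(CATALOGUE) == 47
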