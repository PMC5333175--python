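"""Published reference tables shipped as package constants.

These are small printed summary tables from the genome-annotation literature,
used as inputs: the hg19 Hi-C nuclear-subcompartment domain geometry, the
CGI-vs-gene 100 kb-bin presence contingency tables for human (hg19), mouse
(mm10) and dog (canFam3), per-class Alu densities, and genome-wide bin-count
summaries of the five element types. They parameterize the synthetic-data
generator and serve as direct inputs to the contingency/chi-square analyses;
nothing in the analysis code depends on them.
"""

from __future__ import annotations

from .distribution_stats import ContingencyTable2x2

#: hg19 nuclear subcompartment (TAD class) geometry:
#: class -> (n_domains, mean_length_kb, sd_length_kb, total_length_mb)
SUBCOMPARTMENT_GEOMETRY: dict[str, tuple[int, float, float, float]] = {
    "A1": (490, 818.0, 1217.0, 400.6),
    "A2": (1249, 465.0, 547.0, 581.4),
    "B1": (896, 390.0, 427.0, 349.4),
    "B2": (504, 864.0, 1164.0, 435.7),
    "B3": (685, 1249.0, 1639.0, 855.5),
    "B4": (25, 440.0, 495.0, 11.0),
    "NA": (215, 1157.0, 3404.0, 248.7),
}

#: Genome total spanned by the partition, Mb.
SUBCOMPARTMENT_TOTAL_MB = 2882.3

#: CGI-presence x gene-presence contingency over 100 kb bins, per species.
#: Cells: a = no genes & no CGIs, b = gene only, c = CGI only, d = both.
CGI_GENE_CONTINGENCY: dict[str, ContingencyTable2x2] = {
    "human": ContingencyTable2x2(a=12684, b=4759, c=2267, d=9544),
    "mouse": ContingencyTable2x2(a=13276, b=4910, c=1259, d=7184),
    "dog": ContingencyTable2x2(a=11309, b=3454, c=3361, d=8896),
}

#: hg19 Alu density (elements per 100 kb) by subcompartment class.
ALU_CLASS_DENSITY: dict[str, float] = {
    "A1": 66.0, "A2": 42.0, "B1": 44.0, "B2": 34.0, "B3": 30.0, "B4": 110.0,
}

#: hg19 per-100kb-bin count summaries: element -> (avg, median, sd, min, max).
ELEMENT_BIN_SUMMARY: dict[str, tuple[float, float, float, int, int]] = {
    "L1": (32.6, 31.0, 14.3, 1, 211),
    "DHS": (101.8, 89.0, 62.7, 1, 341),
    "CGI": (1.8, 1.0, 1.5, 1, 21),
    "Alu": (40.9, 26.0, 35.5, 1, 235),
    "gene": (2.3, 2.0, 2.0, 1, 53),
}

#: Human genome GC content used for the expected-CpG-frequency calculation.
HUMAN_GC_CONTENT = 0.42
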