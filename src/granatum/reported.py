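"""Published summary values from the pomegranate 'Sanbai' study.

These printed numbers are *inputs* to the package's summary and interval
arithmetic (category sums, cross-method support percentages, interval
spans, overlap percentages) — the underlying sequencing data are not
redistributed here.
"""

# Non-redundant SVs between the 'Sanbai' and 'Tunisia' assemblies, by type
SV_TYPE_COUNTS = {
    "DEL": 11_043,
    "DUP": 650,
    "INS": 16_197,
    "INV": 117,
    "CNV": 205,
    "TRA": 395,
}

# Cross-method support: DELs/DUPs/INVs from genome comparison vs SMRT mapping
GENOME_COMPARISON_DDI = 6_593
SMRT_MAPPING_DDI = 8_902
CROSS_SUPPORTED_DDI = 3_685

# Assembly and sweep-scan totals
ASSEMBLY_BP = 318_590_000           # 318.59 Mb
SNP_SWEEP_GENOME_FRACTION = 0.0785  # SNP-based sweeps: 7.85% of the assembly
SV_SWEEP_GENOME_FRACTION = 0.0377
SNP_SV_SWEEP_OVERLAP_BP = 17_420_000  # 17.42 Mb

# Chromosome-1 inversion breakpoints (two reported delineations)
INVERSION_PRIMARY = ("Chr1", 18_658_790, 24_069_667)   # read-alignment span
INVERSION_REFINED = ("Chr1", 19_432_846, 23_421_050)
SECOND_INVERSION = ("Chr1", 36_776_860, 38_211_514)

# Cross-population candidate QTL regions
QTL_REGIONS = (
    ("Chr1", 45_730_000, 45_900_000),
    ("Chr1", 50_110_000, 50_480_000),
    ("Chr8", 16_820_000, 17_040_000),
)
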