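"""Heterotrimeric G-protein candidate gene set and published cohort-level inputs.

The candidate set comprises the 27 GNA*/GNB*/GNG* genes coding for the alpha,
beta and gamma subunits of heterotrimeric G proteins.  ``GENE_TEMPLATE`` holds,
per gene, the published start/stop coordinates (bp) and the number of SNPs the
gene contributed to the imputed gene-based analyses; these counts serve as the
sampling template when the synthetic fixture allocates SNPs to genes.
Chromosome and strand assignments are synthetic-plausible stand-ins (chromosome
follows the gene's real location; strand is fixed arbitrarily) — the fixture is
a statistical emulation, not a genome annotation.

``SET_TEST_RESULTS`` records the published cohort-level empirical p-values and
sample sizes for the self-contained set test of this gene set against fluid
ability, crystallised ability and age-11 IQ in the five CAGES cohorts
(Lothian Birth Cohorts 1921/1936, Aberdeen Birth Cohort 1936, Newcastle,
Manchester).  They are inputs to the square-root-N weighted Stouffer
meta-analysis, which combines per-cohort evidence into a single p-value.
"""

from __future__ import annotations

# gene, chrom, n_snps (template count), start, stop, strand
GENE_TEMPLATE: list[tuple[str, str, int, int, int, str]] = [
    ("GNA11", "19", 69, 3045407, 3072454, "+"),
    ("GNA12", "7", 228, 2734266, 2850485, "-"),
    ("GNA13", "17", 54, 60437294, 60483216, "+"),
    ("GNA14", "9", 311, 79228367, 79453043, "-"),
    ("GNA15", "19", 88, 3087190, 3114766, "+"),
    ("GNAI1", "7", 186, 79602075, 79686661, "-"),
    ("GNAI2", "3", 32, 50248650, 50271790, "+"),
    ("GNAI3", "1", 102, 109892708, 109939975, "-"),
    ("GNAL", "18", 258, 11679264, 11871919, "+"),
    ("GNAO1", "16", 241, 54782751, 54948857, "-"),
    ("GNAQ", "9", 271, 79525010, 79836012, "+"),
    ("GNAS", "20", 127, 56848189, 56919645, "-"),
    ("GNAT1", "3", 34, 50204046, 50208953, "+"),
    ("GNAZ", "22", 138, 21742668, 21797221, "-"),
    ("GNB1", "1", 52, 1706588, 1812355, "+"),
    ("GNB2", "7", 35, 100109310, 100114728, "-"),
    ("GNB3", "12", 72, 6819635, 6826818, "+"),
    ("GNB4", "3", 94, 180596569, 180652065, "-"),
    ("GNB5", "15", 137, 50200414, 50270857, "+"),
    ("GNG10", "9", 130, 113463681, 113472347, "-"),
    ("GNG11", "7", 121, 93388951, 93393762, "+"),
    ("GNG12", "1", 239, 67939736, 68071730, "-"),
    ("GNG2", "14", 392, 51396799, 51506268, "+"),
    ("GNG3", "11", 38, 62231708, 62233246, "-"),
    ("GNG4", "1", 148, 233777607, 233880677, "+"),
    ("GNG5", "1", 136, 84736593, 84744850, "-"),
    ("GNG7", "19", 143, 2462217, 2653746, "+"),
]

CANDIDATE_GENES: list[str] = [row[0] for row in GENE_TEMPLATE]

#: genotyped-panel size of the candidate SNP set (per-cohort counts were 468-470)
CANDIDATE_PANEL_SIZE = 470

# phenotype -> list of (cohort, N, n_snps, empirical p)
SET_TEST_RESULTS: dict[str, list[tuple[str, int, int, float]]] = {
    "fluid": [
        ("LBC1921", 505, 468, 0.68),
        ("LBC1936", 989, 468, 0.76),
        ("ABC1936", 350, 470, 0.62),
        ("Newcastle", 754, 469, 0.18),
        ("Manchester", 805, 469, 0.20),
    ],
    "crystallised": [
        ("LBC1921", 515, 468, 0.66),
        ("LBC1936", 1003, 468, 0.97),
        ("ABC1936", 420, 470, 0.63),
        ("Newcastle", 750, 469, 0.90),
        ("Manchester", 770, 469, 0.57),
    ],
    "age11_iq": [
        ("LBC1921", 464, 468, 0.90),
        ("LBC1936", 947, 468, 0.70),
    ],
}

#: cohort sample sizes for the fluid-ability analyses, used by the power study
FLUID_COHORT_SIZES: dict[str, int] = {
    name: n for name, n, _, _ in SET_TEST_RESULTS["fluid"]
}
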