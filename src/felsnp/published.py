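"""Published summary statistics of the eight-cat feline SNP resource.

These tables are the printed endpoints of the genome-scale study this package
models: per-cat read and SNP tallies from the fosmid-end Sanger sequencing of
six domestic breed cats, one African wildcat (Nancy) and the deeply sequenced
inbred Abyssinian reference cat (Cinnamon); per-chromosome SNP counts in the
three discoverer categories (A: excluding sites found only in Cinnamon and/or
Nancy; B: excluding sites found only in Cinnamon; C: all sites); and the PCR
re-sequencing validation tallies.  They serve as fixed inputs for the
arithmetic the statistics modules recompute — none of the package's own
computations are read from here.
"""

from __future__ import annotations

# (cat, breed/population, reads, SNPs, bases per SNP, sex)
PER_CAT = [
    ("Pixel", "Burmese", 331_813, 174_212, 524, "F"),
    ("Zeelie", "Persian", 298_332, 174_706, 510, "F"),
    ("Tipper", "Cornish Rex", 272_607, 164_054, 503, "M"),
    ("Scooter", "Ragdoll", 298_409, 168_455, 510, "M"),
    ("Speedy", "Domestic Shorthair", 310_364, 158_148, 569, "F"),
    ("Cocoa", "Siamese", 293_712, 152_984, 516, "F"),
    ("Nancy", "African wildcat", 1_373_060, 938_386, 360, "F"),
    ("Cinnamon", "Abyssinian", 8_186_934, 1_323_794, 1520, "F"),
]

DOMESTIC_BREED_CATS = ["Pixel", "Zeelie", "Tipper", "Scooter", "Speedy", "Cocoa"]
WILDCAT = "Nancy"
INBRED_CAT = "Cinnamon"

#: Distinct variant sites after merging discoveries across cats.
NON_REDUNDANT_SNP_TOTAL = 3_077_846
#: Short deletion/insertion polymorphisms detected alongside the SNPs.
DIP_TOTAL = 682_085

# Per-chromosome resource table:
# (chromosome, non-N bases, count A, count B, count C,
#  bases-per-SNP A, bases-per-SNP B, bases-per-SNP C)
PER_CHROMOSOME = [
    ("chrA1", 164_170_763, 77_824, 151_421, 240_266, 2_110, 1_084, 683),
    ("chrA2", 120_172_290, 59_782, 118_896, 180_685, 2_010, 1_011, 665),
    ("chrA3", 109_094_838, 55_010, 110_129, 192_266, 1_983, 991, 567),
    ("chrB1", 131_184_541, 62_260, 118_189, 196_456, 2_107, 1_110, 668),
    ("chrB2", 101_553_943, 49_898, 95_152, 161_014, 2_035, 1_067, 631),
    ("chrB3", 96_970_780, 47_679, 93_489, 167_719, 2_034, 1_037, 578),
    ("chrB4", 108_425_265, 53_709, 104_123, 170_033, 2_019, 1_041, 638),
    ("chrC1", 160_223_031, 76_483, 147_928, 245_762, 2_095, 1_083, 652),
    ("chrC2", 107_198_630, 53_479, 98_226, 163_338, 2_004, 1_091, 656),
    ("chrD1", 81_705_395, 45_881, 88_125, 130_989, 1_781, 927, 624),
    ("chrD2", 67_243_459, 37_877, 71_535, 134_493, 1_775, 940, 500),
    ("chrD3", 71_434_721, 40_297, 79_074, 119_894, 1_773, 903, 596),
    ("chrD4", 67_338_148, 34_295, 65_034, 88_513, 1_963, 1_035, 761),
    ("chrE1", 44_074_055, 24_513, 50_193, 87_236, 1_798, 878, 505),
    ("chrE2", 50_431_338, 27_836, 56_317, 94_520, 1_812, 895, 534),
    ("chrE3", 36_523_145, 24_444, 47_449, 68_476, 1_494, 770, 533),
    ("chrF1", 45_373_584, 24_292, 45_507, 83_877, 1_868, 997, 541),
    ("chrF2", 56_475_142, 29_011, 55_998, 93_247, 1_947, 1_009, 606),
    ("chrX", 83_845_181, 19_431, 32_619, 65_352, 4_315, 2_570, 1_283),
    ("chrUnCf", 217_904_849, 101_325, 198_166, 323_505, 2_151, 1_100, 674),
    ("chrUn", 70_839_159, 18_959, 34_246, 70_797, 3_736, 2_069, 1_001),
]

GENOME_TOTAL = ("Total", 1_992_182_257, 964_285, 1_861_816, 3_078_438, 2_066, 1_070, 647)

# PCR re-sequencing validation tallies (94 SNP amplimers, 45 DIPs in amplicons).
SNP_VALIDATION = {"confirmed": 92, "low_quality": 1, "unconfirmed": 1}
DIP_VALIDATION = {"validated": 43, "not_tested": 1, "failed": 1}

# Genotype-based informativeness tallies from the validation experiment.
GENOTYPED_VARIANTS = 92
SINGLETON_VARIANTS = 24            # alternate allele seen in exactly one cat
DOMESTIC_GENOTYPED_VARIANTS = 57   # subset discovered from domestic cat samples
DOMESTIC_MULTI_CAT_VARIANTS = 50   # of those, seen in two or more cats

# Candidate-sampling funnel of the validation experiment.
SAMPLED_CANDIDATES = 555
TESTABLE_AFTER_GAP_FILTER = 393    # at least 750 bases from a contig gap
WITH_DESIGNABLE_PRIMERS = 348

# Assembly-level figures.
CONTIG_N50 = 4_600
TOTAL_ASSEMBLED_BASES = 2_000_000_000
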