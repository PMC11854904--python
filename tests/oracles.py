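"""Independent allele-counting oracle for expected cBAF levels.

Enumerates, for a parental genotype pair and a chromosome copy composition,
every achievable embryo BAF level as (#B alleles)/(#copies).  This is pure
combinatorics over transmitted haplotypes — deliberately independent of the
simulator's dose pipeline and of the classifier.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

# transmission modes: how many copies a parent contributes and which
# haplotype combinations are achievable
#   single: one of the two haplotypes
#   both:   one copy of each haplotype (BPH)
#   dup:    one haplotype duplicated (SPH / isodisomy)
#   none:   no contribution
_GENO_HAPS = {"AA": (0, 0), "AB": (0, 1), "BB": (1, 1)}


def _b_count_options(genotype: str, mode: str) -> set[tuple[int, int]]:
    """Set of (B-count, n_copies) achievable for one parent."""
    h = _GENO_HAPS[genotype]
    if mode == "none":
        return {(0, 0)}
    if mode == "single":
        return {(h[0], 1), (h[1], 1)}
    if mode == "both":
        return {(h[0] + h[1], 2)}
    if mode == "dup":
        return {(2 * h[0], 2), (2 * h[1], 2)}
    raise ValueError(mode)


def expected_baf_levels(pat_geno: str, mat_geno: str,
                        pat_mode: str, mat_mode: str) -> set[Fraction]:
    """All achievable embryo BAF levels for one SNP class and karyotype."""
    levels = set()
    for (pb, pn), (mb, mn) in product(_b_count_options(pat_geno, pat_mode),
                                      _b_count_options(mat_geno, mat_mode)):
        total = pn + mn
        if total:
            levels.add(Fraction(pb + mb, total))
    return levels


#: subcategory -> (paternal genotype, maternal genotype)
SUBCAT_GENOS = {
    "1A": ("BB", "AA"), "1B": ("AA", "BB"),
    "2A": ("BB", "AB"), "2B": ("AA", "AB"),
    "3A": ("AB", "BB"), "3B": ("AB", "AA"),
    "4A": ("BB", "BB"), "4B": ("AA", "AA"),
}

#: karyotype column -> (paternal mode, maternal mode); maternal-origin events
KARYOTYPES = {
    "disomy": ("single", "single"),
    "maternal_monosomy": ("single", "none"),
    "maternal_trisomy_SPH": ("single", "dup"),
    "maternal_trisomy_BPH": ("single", "both"),
    "maternal_UPD_hetero": ("none", "both"),
    "maternal_UPD_iso": ("none", "dup"),
}


def expected_levels_for(karyotype: str, subcategory: str) -> set[float]:
    pat_mode, mat_mode = KARYOTYPES[karyotype]
    pg, mg = SUBCAT_GENOS[subcategory]
    return {float(x) for x in expected_baf_levels(pg, mg, pat_mode, mat_mode)}


def expected_log2r(karyotype: str) -> float:
    import math
    pat_mode, mat_mode = KARYOTYPES[karyotype]
    copies = {"none": 0, "single": 1, "both": 2, "dup": 2}
    total = copies[pat_mode] + copies[mat_mode]
    return math.log2(total / 2.0)
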