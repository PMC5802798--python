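"""Within-population diversity: haplotype diversity and nucleotide diversity.

Haplotype diversity HD = n(1 - sum p_i^2)/(n - 1) with the Nei (1987)
sampling variance; nucleotide diversity pi as the mean per-site pairwise
difference under pairwise deletion of non-called positions, with the
Tajima (1983) total variance (stochastic + sampling). These are the
estimators implemented by the classical population-genetics toolchain for
haplotypic mtDNA data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seqio import CALLED_BASES


@dataclass(frozen=True)
class DiversityResult:
    estimate: float
    standard_deviation: float
    n: int
    L: int  # sites used (region length; per-pair called counts may differ)

    def __iter__(self):  # (estimate, sd) unpacking convenience
        return iter((self.estimate, self.standard_deviation))


def haplotype_diversity(haplotypes) -> DiversityResult:
    """Unbiased gene/haplotype diversity over exact-match haplotype classes.

    Identity is exact string equality after uppercasing; an ``N`` never
    matches anything, so partially called sequences form their own classes
    rather than silently merging.
    """
    haps = [h.upper() for h in haplotypes]
    n = len(haps)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    counts = np.array(list(Counter(haps).values()), dtype=float)
    p = counts / n
    sum_p2 = float(np.sum(p ** 2))
    sum_p3 = float(np.sum(p ** 3))
    hd = n * (1.0 - sum_p2) / (n - 1)
    # Nei (1987) eq. 8.12 sampling variance of the heterozygosity estimator.
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2 ** 2) + sum_p2 - sum_p2 ** 2
    )
    var = max(var, 0.0)
    L = len(haps[0]) if haps else 0
    return DiversityResult(hd, float(np.sqrt(var)), n, L)


def pairwise_difference(a: str, b: str) -> tuple[int, int]:
    """(differences, jointly called sites) under pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    diffs = called = 0
    for x, y in zip(a, b):
        if x in CALLED_BASES and y in CALLED_BASES:
            called += 1
            if x != y:
                diffs += 1
    return diffs, called


def nucleotide_diversity(sequences, complete_deletion: bool = False) -> DiversityResult:
    """Mean per-site pairwise nucleotide diversity.

    With pairwise deletion (default) each pair is scored over its own
    jointly called positions and pi is the mean of per-pair per-site
    proportions — robust to the ragged coverage of ancient consensus
    sequences. ``complete_deletion`` restricts all pairs to the columns
    called in every sequence first.
    """
    seqs = [s.upper() for s in sequences]
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    L_region = len(seqs[0])
    if complete_deletion:
        keep = [i for i in range(L_region)
                if all(s[i] in CALLED_BASES for s in seqs)]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    props = []
    for a, b in combinations(seqs, 2):
        d, called = pairwise_difference(a, b)
        if called == 0:
            raise ValueError("a sequence pair shares no called positions")
        props.append(d / called)
    pi = float(np.mean(props))
    # Tajima (1983) total variance; L enters through the per-site term.
    L = len(seqs[0])
    var = ((n + 1) / (3.0 * (n - 1))) * pi / L \
        + (2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))) * pi * pi
    return DiversityResult(pi, float(np.sqrt(var)), n, L)
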