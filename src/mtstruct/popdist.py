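"""Sequence distances, pairwise population PhiST, permutation inference,
Benjamini-Hochberg correction and MDS embedding.

Pairwise population "Fst" here is the AMOVA-based PhiST computed from the
two-level variance decomposition on squared sequence distances — the
convention of the classical haplotypic-data toolchain. Slatkin's
linearization D = Fst/(1-Fst) turns it into a quantity proportional to
divergence time under an island model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import log

import numpy as np

from . import amova as _amova
from .seqio import CALLED_BASES

DISTANCE_MODELS = ("differences", "p", "TN93", "TN93+G")


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "dissimilarity"  # sequence | population_fst | dissimilarity

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise DistanceError("matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise DistanceError("matrix entries must be finite")
        self.values = v

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, kind="dissimilarity"):
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), kind)


# ---------------------------------------------------------------------------
# Sequence-level distances
# ---------------------------------------------------------------------------

def _pair_counts(a: str, b: str):
    """Transition/transversion bookkeeping over jointly called sites."""
    n = p1 = p2 = q = 0
    base_counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a, b):
        if x not in CALLED_BASES or y not in CALLED_BASES:
            continue
        n += 1
        base_counts[x] += 1
        base_counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    return n, p1, p2, q, base_counts


def seq_distance(a: str, b: str, model: str = "differences",
                 gamma_shape: float | None = None) -> float:
    """Distance between two rCRS-aligned sequences over jointly called sites.

    ``differences``: raw count; ``p``: proportion; ``TN93``: Tamura-Nei
    closed form; ``TN93+G``: its gamma-rate correction with user-supplied
    shape. Saturated pairs (logarithm domain violations) raise.
    """
    if len(a) != len(b):
        raise DistanceError("sequences must have equal length")
    if model not in DISTANCE_MODELS:
        raise DistanceError(f"unknown model {model!r}")
    a, b = a.upper(), b.upper()
    n, p1, p2, q, base_counts = _pair_counts(a, b)
    if n == 0:
        raise DistanceError("no jointly called sites")
    if model == "differences":
        return float(p1 + p2 + q)
    if model == "p":
        return (p1 + p2 + q) / n

    total = sum(base_counts.values())
    fa, fc, fg, ft = (base_counts[x] / total for x in "ACGT")
    fr, fy = fa + fg, fc + ft
    if min(fa, fc, fg, ft) == 0.0:
        # Degenerate composition: fall back to the substitution proportion,
        # the standard limit behaviour when a class frequency vanishes.
        return (p1 + p2 + q) / n
    P1, P2, Q = p1 / n, p2 / n, q / n
    k1 = 2 * fa * fg / fr
    k2 = 2 * fc * ft / fy
    k3 = 2 * (fr * fy - fa * fg * fy / fr - fc * ft * fr / fy)
    w1 = 1 - P1 / k1 - Q / (2 * fr)
    w2 = 1 - P2 / k2 - Q / (2 * fy)
    w3 = 1 - Q / (2 * fr * fy)
    if min(w1, w2, w3) <= 0:
        raise DistanceError("TN93 saturated pair (logarithm domain violation)")
    if model == "TN93":
        return -k1 * log(w1) - k2 * log(w2) - k3 * log(w3)
    if gamma_shape is None or gamma_shape <= 0:
        raise DistanceError("TN93+G requires a positive gamma shape")
    alpha = gamma_shape
    inv = lambda w: w ** (-1.0 / alpha) - 1.0
    return alpha * (k1 * inv(w1) + k2 * inv(w2) + k3 * inv(w3))


def squared_distance_matrix(sequences, model: str = "differences",
                            gamma_shape: float | None = None) -> np.ndarray:
    """Squared pairwise distances as they enter AMOVA. With the
    ``differences`` model the squared distance is the difference count
    itself (haplotypic convention); metric models are squared."""
    n = len(sequences)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = seq_distance(sequences[i], sequences[j], model, gamma_shape)
            out[i, j] = out[j, i] = d if model == "differences" else d * d
    return out


def sequence_distance_matrix(dataset, model: str = "differences",
                             gamma_shape: float | None = None) -> DistanceMatrix:
    seqs = [r.sequence for r in dataset.records]
    n = len(seqs)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = seq_distance(seqs[i], seqs[j], model, gamma_shape)
    return DistanceMatrix([r.sample_id for r in dataset.records], vals, "sequence")


# ---------------------------------------------------------------------------
# Population PhiST
# ---------------------------------------------------------------------------

def _two_pop_phist(d2: np.ndarray, idx: np.ndarray) -> float:
    res = _amova._decompose(_amova._PairSums(d2, idx, 2), [[0, 1]])
    return res.phi_st


def pairwise_phist(dataset, model: str = "differences",
                   gamma_shape: float | None = None) -> DistanceMatrix:
    """Pairwise PhiST between all populations via the two-level AMOVA;
    negative values are retained."""
    pops = dataset.populations
    if len(pops) < 2:
        raise DistanceError("need >= 2 populations")
    small = [p for p in pops if len(dataset.population(p)) < 2]
    if small:
        raise DistanceError(f"populations with < 2 members: {small}")
    seqs_by_pop = {p: [r.sequence for r in dataset.population(p)] for p in pops}
    vals = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            seqs = seqs_by_pop[pops[i]] + seqs_by_pop[pops[j]]
            idx = np.array([0] * len(seqs_by_pop[pops[i]]) + [1] * len(seqs_by_pop[pops[j]]))
            d2 = squared_distance_matrix(seqs, model, gamma_shape)
            vals[i, j] = vals[j, i] = _two_pop_phist(d2, idx)
    return DistanceMatrix(list(pops), vals, "population_fst")


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearized distance D = Fst/(1 - Fst)."""
    if fst >= 1.0:
        raise DistanceError("Fst = 1 linearizes to infinity")
    return fst / (1.0 - fst)


def fst_permutation_p(dataset, pair, n_perm: int = 999, seed: int = 0,
                      model: str = "differences",
                      gamma_shape: float | None = None) -> float:
    """One-pair permutation p-value: individuals shuffled between the two
    populations holding sizes fixed; p = (1+#{>= observed})/(n_perm+1)."""
    if n_perm < 1:
        raise DistanceError("n_perm must be >= 1")
    a, b = pair
    seqs = [r.sequence for r in dataset.population(a)] + \
           [r.sequence for r in dataset.population(b)]
    na = len(dataset.population(a))
    idx = np.array([0] * na + [1] * (len(seqs) - na))
    d2 = squared_distance_matrix(seqs, model, gamma_shape)
    obs = _two_pop_phist(d2, idx)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if _two_pop_phist(d2, rng.permutation(idx)) >= obs - 1e-12:
            ge += 1
    return (1 + ge) / (n_perm + 1)


@dataclass
class FstResult:
    fst: DistanceMatrix
    linearized: DistanceMatrix
    pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    n_permutations: int
    seed: int
    model: str = "differences"

    def write(self, outdir) -> None:
        from pathlib import Path
        import pandas as pd
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fst.write_tsv(outdir / "fst.tsv")
        self.linearized.write_tsv(outdir / "fst_linearized.tsv")
        labels = self.fst.labels
        pd.DataFrame(self.pvalues, index=labels, columns=labels).to_csv(
            outdir / "pvalues.tsv", sep="\t")
        pd.DataFrame(self.adjusted_pvalues, index=labels, columns=labels).to_csv(
            outdir / "pvalues_bh.tsv", sep="\t")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"model": self.model, "n_permutations": self.n_permutations,
                       "seed": self.seed}, fh, indent=2)


def compute_fst(dataset, model: str = "differences", n_perm: int = 999,
                seed: int = 0, gamma_shape: float | None = None) -> FstResult:
    """Full pairwise PhiST analysis: matrix, permutation p-values on each
    pair (seed offset by pair index for independence and reproducibility),
    BH adjustment over the strict lower triangle, Slatkin linearization."""
    fst = pairwise_phist(dataset, model, gamma_shape)
    k = len(fst.labels)
    pvals = np.ones((k, k))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for rank, (i, j) in enumerate(pairs):
        p = fst_permutation_p(dataset, (fst.labels[i], fst.labels[j]),
                              n_perm=n_perm, seed=seed + rank, model=model,
                              gamma_shape=gamma_shape)
        pvals[i, j] = pvals[j, i] = p
    flat = np.array([pvals[i, j] for i, j in pairs])
    adj_flat = bh_adjust(flat)
    adj = np.ones((k, k))
    for (i, j), v in zip(pairs, adj_flat):
        adj[i, j] = adj[j, i] = v
    lin_vals = np.vectorize(slatkin_linearize)(fst.values) if k else fst.values
    np.fill_diagonal(lin_vals, 0.0)
    linearized = DistanceMatrix(fst.labels, lin_vals, "population_fst")
    return FstResult(fst, linearized, pvals, adj, n_perm, seed, model)


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values: sorted cumulative
    minimum of m*p/rank, capped at 1, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise DistanceError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.reshape(np.shape(pvalues))


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

def _prepare_dissimilarity(dm: DistanceMatrix) -> np.ndarray:
    """Fst matrices: clamp negative entries to 0 and zero the diagonal —
    negative Fst is statistically indistinguishable from no differentiation
    and nonmetric stress needs non-negative dissimilarities."""
    d = dm.values.copy()
    if dm.kind == "population_fst":
        d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(d: np.ndarray, dims: int = 2):
    """Principal-coordinates analysis: eigen-decomposition of the double-
    centered squared dissimilarity matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.maximum(evals[:dims], 0.0)
    return evecs[:, :dims] * np.sqrt(pos)


def _stress1(coords: np.ndarray, d: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform
    from sklearn.isotonic import IsotonicRegression
    emb = squareform(pdist(coords))
    iu = np.triu_indices_from(d, k=1)
    x, y = d[iu], emb[iu]
    fitted = IsotonicRegression().fit_transform(x, y)
    denom = float(np.sum(y ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((y - fitted) ** 2) / denom))


def mds_embed(dm: DistanceMatrix, dims: int = 2, mode: str = "nonmetric",
              seed: int = 0, n_restarts: int = 4):
    """Embed a dissimilarity matrix; returns (coordinates, stress-1).

    ``classical`` runs principal coordinates; ``nonmetric`` runs SMACOF
    with isotonic regression, seeded random restarts plus one classical-
    initialized run, returning the lowest-stress solution.
    """
    n = len(dm.labels)
    if dims > n - 1:
        raise DistanceError(f"dims={dims} > n-1={n - 1}")
    if mode not in ("classical", "nonmetric"):
        raise DistanceError(f"unknown MDS mode {mode!r}")
    d = _prepare_dissimilarity(dm)
    coords = classical_mds(d, dims)
    if mode == "classical":
        return coords, _stress1(coords, d)

    from sklearn.manifold import smacof

    best_coords, best_stress = None, np.inf
    inits = [coords] + [None] * n_restarts
    for k, init in enumerate(inits):
        c, _ = smacof(d, metric=False, n_components=dims, init=init,
                      n_init=1, random_state=seed + k, normalized_stress=True,
                      eps=1e-9, max_iter=500)
        s = _stress1(c, d)
        if s < best_stress:
            best_coords, best_stress = c, s
    return best_coords, best_stress
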