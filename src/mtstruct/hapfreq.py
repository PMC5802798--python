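"""Haplogroup binning, frequency matrices, Ward clustering with bootstrap
support, PCA with loadings, metapopulation resampling and R x C testing.

Bin schemes collapse Phylotree-style haplogroup labels (e.g. ``U5a1d1``)
into coarse frequency categories by longest-prefix matching, with
macro-class bins (Asian / African founder clades) matched by first
letter. Three shipped schemes cover the Central European transect
(CEPT23), the pan-European ancient transect (EPT25) and the worldwide
modern panel (WORLD23).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln
from scipy.stats import fisher_exact, random_table


class HapFreqError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bin schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    name: str
    bins: tuple[str, ...]                   # declared order, "others" last
    prefix_rules: tuple[tuple[str, str], ...]   # (label prefix, bin)
    macro_rules: tuple[tuple[str, str], ...] = ()  # (first-letter set, bin)
    fallback: str = "others"

    def __post_init__(self) -> None:
        declared = set(self.bins)
        for _, b in self.prefix_rules + self.macro_rules:
            if b not in declared:
                raise HapFreqError(f"rule maps to undeclared bin {b!r}")
        if self.fallback not in declared:
            raise HapFreqError("fallback bin must be declared")

    def assign(self, haplogroup_label: str) -> str:
        return assign_bin(haplogroup_label, self)


def _prefix_scheme(name: str, prefixes, macro=(), extra_bins=()) -> BinScheme:
    """Build a scheme where each simple bin matches labels by its own name
    as prefix; longest prefix wins, so 'H5' beats 'H' and 'U5a' beats 'U'."""
    rules = tuple(sorted(((p, b) for p, b in prefixes), key=lambda r: -len(r[0])))
    bins = tuple(dict.fromkeys([b for _, b in prefixes] + [b for _, b in macro]
                               + list(extra_bins) + ["others"]))
    return BinScheme(name, bins, rules, tuple(macro))


def _simple(*names):
    return [(n, n) for n in names]

# Central European transect: 23 bins.
CEPT23 = _prefix_scheme(
    "CEPT23",
    _simple("H", "H5", "HV", "HV0", "V", "I", "J", "K", "N", "N1a", "R",
            "T1", "T2", "U", "U2", "U3", "U4", "U5a", "U5b", "U8", "W", "X"),
)

# Pan-European ancient transect with an Asian macro-bin.
EPT25 = _prefix_scheme(
    "EPT25",
    _simple("N", "N1a", "I", "J", "W", "X", "R", "HV", "H", "H5",
            "T", "T1", "T2", "U", "U2", "U3", "U4", "U5a", "U5b", "U8", "K")
    + [("V", "V/HV0"), ("HV0", "V/HV0")],
    macro=[("ACDFGZ", "Asian")],
)

# Worldwide modern panel with Asian and African macro-bins.
WORLD23 = _prefix_scheme(
    "WORLD23",
    _simple("N1a", "I", "I1", "W", "X", "HV", "H", "H5",
            "T1", "T2", "J", "U", "U2", "U3", "U4", "U5a", "U5b", "U8", "K")
    + [("V", "V/HV0"), ("HV0", "V/HV0")],
    macro=[("ACDFGZ", "Asian"), ("L", "African")],
)

SCHEMES = {s.name: s for s in (CEPT23, EPT25, WORLD23)}


def assign_bin(haplogroup_label: str, scheme: BinScheme) -> str:
    """Longest-matching-prefix bin assignment; total (never fails) and
    idempotent (bin labels map to themselves where declared)."""
    label = haplogroup_label.strip().upper()
    if not label:
        raise HapFreqError("empty haplogroup label")
    for prefix, bin_name in scheme.prefix_rules:  # sorted longest-first
        if label.startswith(prefix.upper()):
            return bin_name
    for letters, bin_name in scheme.macro_rules:
        if label[0] in letters:
            return bin_name
    return scheme.fallback


def scheme_from_yaml(path) -> BinScheme:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _prefix_scheme(raw["name"],
                          [(p, b) for p, b in raw["prefix_rules"]],
                          [(letters, b) for letters, b in raw.get("macro_rules", [])])


# ---------------------------------------------------------------------------
# Frequency matrices
# ---------------------------------------------------------------------------

@dataclass
class FrequencyMatrix:
    counts: pd.DataFrame  # populations x bins, non-negative integers

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise HapFreqError("counts must be non-negative")

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def bins(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def frequencies(self) -> pd.DataFrame:
        # A zero row total (possible under column resampling) yields an
        # all-zero frequency row rather than NaNs.
        totals = self.counts.sum(axis=1).replace(0, 1)
        return self.counts.div(totals, axis=0)

    @classmethod
    def from_frequencies(cls, freq: pd.DataFrame, scale: int = 1000) -> "FrequencyMatrix":
        """Wrap a row-normalized frequency table (e.g. a synthetic Dirichlet
        draw) by scaling to pseudo-counts; used where only frequencies exist."""
        return cls((freq * scale).round().astype(int))

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def build_frequency_matrix(assignments: dict[str, tuple[str, str]],
                           scheme: BinScheme) -> FrequencyMatrix:
    """Tabulate per-population bin counts from
    ``sample_id -> (population, haplogroup label)``; zero-count bins are
    retained so every matrix shares the scheme's column space."""
    if not assignments:
        raise HapFreqError("no assignments")
    pops: dict[str, dict[str, int]] = {}
    for _, (pop, label) in assignments.items():
        row = pops.setdefault(pop, {b: 0 for b in scheme.bins})
        row[assign_bin(label, scheme)] += 1
    counts = pd.DataFrame.from_dict(pops, orient="index").reindex(
        columns=list(scheme.bins), fill_value=0).sort_index()
    return FrequencyMatrix(counts)


def frequency_matrix_from_counts(counts: pd.DataFrame) -> FrequencyMatrix:
    return FrequencyMatrix(counts.copy())


# ---------------------------------------------------------------------------
# Ward clustering + bootstrap support
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray          # scipy (n-1, 4) format
    support: dict[frozenset, float] | None = None  # leaf set -> percent

    def clusters(self) -> list[frozenset]:
        """Leaf sets of the internal nodes, smallest merges first."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ward_cluster(freq: FrequencyMatrix) -> Dendrogram:
    """Agglomerative Ward linkage on Euclidean distances between frequency
    rows (the squared-update "Ward.D2" Lance-Williams variant). Ties are
    broken deterministically by the underlying nearest-neighbor chain."""
    rows = freq.frequencies.to_numpy()
    if rows.shape[0] < 2:
        raise HapFreqError("clustering needs >= 2 populations")
    return Dendrogram(freq.populations, linkage(rows, method="ward"))


def bootstrap_support(freq: FrequencyMatrix, n_boot: int = 1000,
                      seed: int = 0, resample: str = "bins") -> Dendrogram:
    """Bootstrap proportion per internal node: the percentage of replicate
    trees containing the identical leaf set. Default resamples bin columns
    with replacement (feature bootstrap); ``resample='populations'``
    resamples rows instead."""
    if n_boot < 1:
        raise HapFreqError("n_boot must be >= 1")
    base = ward_cluster(freq)
    target = base.clusters()
    hits = {c: 0 for c in target}
    rng = np.random.default_rng(seed)
    counts = freq.counts
    k = counts.shape[1]
    for _ in range(n_boot):
        if resample == "bins":
            cols = rng.integers(k, size=k)
            boot = FrequencyMatrix(counts.iloc[:, cols].set_axis(
                [f"b{i}" for i in range(k)], axis=1))
            rep = ward_cluster(boot)
        elif resample == "populations":
            rows = rng.integers(counts.shape[0], size=counts.shape[0])
            boot = FrequencyMatrix(counts.iloc[rows].set_axis(
                [f"r{i}" for i in range(counts.shape[0])], axis=0))
            rep = Dendrogram(list(counts.index[rows]),
                             linkage(boot.frequencies.to_numpy(), method="ward"))
        else:
            raise HapFreqError(f"unknown resample mode {resample!r}")
        rep_clusters = set(rep.clusters())
        for c in target:
            if c in rep_clusters:
                hits[c] += 1
    support = {c: 100.0 * h / n_boot for c, h in hits.items()}
    return Dendrogram(base.labels, base.linkage_matrix, support)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame          # populations x components
    loadings: pd.DataFrame        # bins x components
    explained_fraction: np.ndarray

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        self.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
        pd.Series(self.explained_fraction, name="explained_fraction").to_csv(
            outdir / "pca_explained.tsv", sep="\t")


def pca_frequencies(freq: FrequencyMatrix) -> PCAResult:
    """Column-centered (unscaled) PCA of frequency rows via SVD; bins share
    a scale by construction, so the covariance convention applies."""
    x = freq.frequencies.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise HapFreqError("PCA needs >= 2 populations")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(x.shape[0] - 1, x.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    var = s ** 2
    total = var.sum()
    explained = var / total if total > 0 else var
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=freq.populations, columns=comps),
        loadings=pd.DataFrame(vt.T, index=freq.bins, columns=comps),
        explained_fraction=explained,
    )


# ---------------------------------------------------------------------------
# Metapopulation resampling
# ---------------------------------------------------------------------------

def build_metapopulation(pool: pd.DataFrame, n: int, seed: int = 0):
    """Uniform sample without replacement of *n* individuals from a pooled
    table of modern reference individuals (columns: at least ``country``
    and ``haplogroup``). Returns (sampled table, per-country tally)."""
    if len(pool) < n:
        raise HapFreqError(f"pool of {len(pool)} smaller than requested {n}")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(pool), size=n, replace=False)
    sample = pool.iloc[np.sort(take)].copy()
    tally = sample["country"].value_counts().to_dict() if "country" in sample else {}
    return sample, tally


# ---------------------------------------------------------------------------
# Fisher R x C
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under the fixed-margins
    (multivariate hypergeometric) null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_rxc(table, n_sim: int = 10000, seed: int = 0) -> float:
    """Fisher's test on an R x C count table: exact two-sided hypergeometric
    p for 2 x 2, Monte-Carlo over fixed-margins tables otherwise with
    p = (1 + #{prob <= observed}) / (n_sim + 1)."""
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise HapFreqError("table must have >= 2 rows and >= 2 columns")
    if (t < 0).any():
        raise HapFreqError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise HapFreqError("all-zero row or column")
    if t.shape == (2, 2):
        return float(fisher_exact(t)[1])
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(t)
    sampler = random_table(t.sum(axis=1), t.sum(axis=0))
    draws = sampler.rvs(size=n_sim, random_state=rng)
    le = sum(1 for d in draws if _log_table_prob(np.asarray(d)) <= obs_logp + 1e-9)
    return (1 + le) / (n_sim + 1)
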