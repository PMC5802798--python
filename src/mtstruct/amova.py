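"""Analysis of molecular variance (AMOVA) with Phi-statistics.

Implements the Excoffier-Smouse-Quattro decomposition of pairwise squared
sequence distances into among-group (sigma_a), among-populations-within-
groups (sigma_b) and within-population (sigma_c) components, with the
standard method-of-moments coefficients for unequal sample sizes, the
three permutation tests, and the grouping-combination optimization that
searches candidate population partitions for maximal among-group (Fct)
and minimal within-group (Fsc) differentiation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import yaml


class AMOVAError(ValueError):
    pass


@dataclass(frozen=True)
class Grouping:
    """A named partition of population ids into disjoint non-empty groups."""

    name: str
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [p for g in self.groups for p in g]
        if not self.groups or any(not g for g in self.groups):
            raise AMOVAError(f"grouping {self.name!r}: empty group")
        if len(set(flat)) != len(flat):
            raise AMOVAError(f"grouping {self.name!r}: population in several groups")

    @property
    def populations(self) -> frozenset:
        return frozenset(p for g in self.groups for p in g)

    def group_index(self) -> dict[str, int]:
        return {p: gi for gi, g in enumerate(self.groups) for p in g}

    @classmethod
    def from_mapping(cls, name: str, mapping: dict) -> "Grouping":
        return cls(name, tuple(tuple(v) for v in mapping.values()))

    def canonical_key(self) -> tuple:
        return tuple(sorted(tuple(sorted(g)) for g in self.groups))


def read_groupings(path) -> list[Grouping]:
    """Candidate grouping file: YAML/JSON list of {name, groups: {gname: [pops]}}
    entries, or a single mapping group-name -> population list."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        return [Grouping.from_mapping("grouping", data)]
    return [Grouping.from_mapping(entry.get("name", f"g{i}"), entry["groups"])
            for i, entry in enumerate(data)]


@dataclass
class AMOVAResult:
    sigma_a: float | None      # among groups; None for a one-group design
    sigma_b: float             # among populations (within groups)
    sigma_c: float             # within populations
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float
    grouping: Grouping | None = None
    negative_components: bool = False
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    df: dict = field(default_factory=dict)
    ss: dict = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return (self.sigma_a or 0.0) + self.sigma_b + self.sigma_c

    def to_manifest(self) -> dict:
        return {
            "sigma_a": self.sigma_a, "sigma_b": self.sigma_b, "sigma_c": self.sigma_c,
            "phi_ct": self.phi_ct, "phi_sc": self.phi_sc, "phi_st": self.phi_st,
            "p_ct": self.p_ct, "p_sc": self.p_sc, "p_st": self.p_st,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "squared_distance_convention": "difference count",
        }


# ---------------------------------------------------------------------------
# Core sums-of-squares machinery
# ---------------------------------------------------------------------------

class _PairSums:
    """Aggregated squared-distance sums: W[p] = sum over pairs within
    population p; B[p, q] = full sum over cross pairs (p != q). Everything
    the three-level decomposition needs, so candidate groupings and
    population-level permutations are O(P^2)."""

    def __init__(self, d2: np.ndarray, pop_index: np.ndarray, n_pops: int):
        z = np.zeros((len(pop_index), n_pops))
        z[np.arange(len(pop_index)), pop_index] = 1.0
        s = z.T @ d2 @ z
        self.between = s - np.diag(np.diag(s))
        self.within = np.diag(s) / 2.0
        self.sizes = z.sum(axis=0)
        self.n_total = int(self.sizes.sum())
        self.total_pair_sum = float(self.within.sum() + self.between.sum() / 2.0)


def _decompose(ps: _PairSums, membership: list[list[int]]) -> AMOVAResult:
    """Variance components for the partition *membership* (population
    indices per group) from precomputed pair sums."""
    n = ps.n_total
    sizes = ps.sizes
    n_pops = len(sizes)
    G = len(membership)

    ssd_total = ps.total_pair_sum / n
    ssd_wp = float(np.sum(ps.within / sizes))
    ssd_wg = 0.0
    group_sizes = []
    sum_np2_over_ng = 0.0
    for members in membership:
        idx = np.asarray(members)
        ng = float(sizes[idx].sum())
        group_sizes.append(ng)
        pair_sum = float(ps.within[idx].sum() + ps.between[np.ix_(idx, idx)].sum() / 2.0)
        ssd_wg += pair_sum / ng
        sum_np2_over_ng += float((sizes[idx] ** 2).sum()) / ng
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_wp = n - n_pops
    if df_wp <= 0:
        raise AMOVAError("within-population df <= 0 (need individuals beyond one per population)")
    sigma_c = ssd_wp / df_wp
    sum_np2 = float((sizes ** 2).sum())

    if G == 1:
        # Two-level decomposition: among populations vs within.
        df_ap = n_pops - 1
        if df_ap == 0:
            raise AMOVAError("two-level AMOVA needs >= 2 populations")
        n_c = (n - sum_np2 / n) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_c
        total = sigma_b + sigma_c
        if total == 0:
            raise AMOVAError("zero total variance: all sequences identical")
        return AMOVAResult(
            sigma_a=None, sigma_b=sigma_b, sigma_c=sigma_c,
            phi_ct=None, phi_sc=None, phi_st=sigma_b / total,
            negative_components=sigma_b < 0,
            df={"among_populations": df_ap, "within_populations": df_wp},
            ss={"among_populations": ssd_ap, "within_populations": ssd_wp,
                "total": ssd_total},
        )

    df_ag = G - 1
    df_ap = n_pops - G
    if df_ap < 0:
        raise AMOVAError("more groups than populations")
    if df_ap == 0:
        sigma_b = 0.0  # one population per group: no within-group level
    else:
        n_prime = (n - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
    n_2 = (sum_np2_over_ng - sum_np2 / n) / df_ag
    n_3 = (n - float(np.sum(np.asarray(group_sizes) ** 2)) / n) / df_ag
    sigma_a = (ssd_ag / df_ag - sigma_c - n_2 * sigma_b) / n_3

    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        raise AMOVAError("zero total variance: all sequences identical")
    return AMOVAResult(
        sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c,
        phi_ct=sigma_a / total,
        phi_sc=sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c != 0 else np.nan,
        phi_st=(sigma_a + sigma_b) / total,
        negative_components=(sigma_a < 0 or sigma_b < 0),
        df={"among_groups": df_ag, "among_populations": df_ap,
            "within_populations": df_wp},
        ss={"among_groups": ssd_ag, "among_populations": ssd_ap,
            "within_populations": ssd_wp, "total": ssd_total},
    )


def _dataset_arrays(dataset, grouping: Grouping, model: str):
    from .popdist import squared_distance_matrix  # local import: popdist uses amova

    pops = [p for p in dataset.populations if p in grouping.populations]
    missing = grouping.populations - set(pops)
    if missing:
        raise AMOVAError(f"grouping references absent populations: {sorted(missing)}")
    records = [r for r in dataset.records if r.population_id in grouping.populations]
    pop_order = sorted(pops)  # ordering-invariant canonical order
    pop_to_idx = {p: i for i, p in enumerate(pop_order)}
    idx = np.array([pop_to_idx[r.population_id] for r in records])
    d2 = squared_distance_matrix([r.sequence for r in records], model)
    gidx = grouping.group_index()
    membership = [[] for _ in grouping.groups]
    for p, i in pop_to_idx.items():
        membership[gidx[p]].append(i)
    return d2, idx, len(pop_order), membership


def variance_components(dataset, grouping: Grouping, model: str = "differences") -> AMOVAResult:
    """Hierarchical variance components and Phi-statistics (no p-values).

    Distances enter as squared Euclidean-like quantities; under the
    default haplotypic ``differences`` model the squared distance IS the
    nucleotide difference count. Negative components are reported as
    computed and flagged, not truncated.
    """
    d2, idx, n_pops, membership = _dataset_arrays(dataset, grouping, model)
    result = _decompose(_PairSums(d2, idx, n_pops), membership)
    result.grouping = grouping
    return result


def amova_permutation(dataset, grouping: Grouping, n_perm: int = 999,
                      seed: int = 0, model: str = "differences") -> AMOVAResult:
    """Permutation p-values for the three Phi-statistics.

    * Phi_ct: whole populations permuted among groups (group sizes in
      populations held fixed);
    * Phi_sc: individuals permuted among populations within groups;
    * Phi_st: individuals permuted among populations ignoring groups.

    Each p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise AMOVAError("n_perm must be >= 1")
    d2, idx, n_pops, membership = _dataset_arrays(dataset, grouping, model)
    ps = _PairSums(d2, idx, n_pops)
    obs = _decompose(ps, membership)
    obs.grouping = grouping
    rng = np.random.default_rng(seed)
    G = len(membership)

    # --- Phi_st: global individual-level permutation -----------------------
    ge_st = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        r = _decompose(_PairSums(d2, perm, n_pops), membership)
        if r.phi_st >= obs.phi_st - 1e-12:
            ge_st += 1
    obs.p_st = (1 + ge_st) / (n_perm + 1)

    if G >= 2:
        # --- Phi_sc: individuals permuted within groups --------------------
        group_of_pop = np.empty(n_pops, dtype=int)
        for gi, members in enumerate(membership):
            group_of_pop[members] = gi
        group_of_ind = group_of_pop[idx]
        ge_sc = 0
        for _ in range(n_perm):
            perm = idx.copy()
            for gi in range(G):
                mask = group_of_ind == gi
                perm[mask] = rng.permutation(perm[mask])
            r = _decompose(_PairSums(d2, perm, n_pops), membership)
            if r.phi_sc >= obs.phi_sc - 1e-12:
                ge_sc += 1
        obs.p_sc = (1 + ge_sc) / (n_perm + 1)

        # --- Phi_ct: populations permuted among groups ---------------------
        sizes_in_pops = [len(m) for m in membership]
        n_distinct = _multinomial(n_pops, sizes_in_pops)
        if n_distinct < n_perm:
            warnings.warn(
                f"only {n_distinct} distinct population-level permutations; "
                f"sampling with replacement", stacklevel=2)
        ge_ct = 0
        for _ in range(n_perm):
            order = rng.permutation(n_pops)
            perm_membership, at = [], 0
            for size in sizes_in_pops:
                perm_membership.append(list(order[at: at + size]))
                at += size
            r = _decompose(ps, perm_membership)
            if r.phi_ct >= obs.phi_ct - 1e-12:
                ge_ct += 1
        obs.p_ct = (1 + ge_ct) / (n_perm + 1)

    obs.n_permutations = n_perm
    obs.seed = seed
    return obs


def _multinomial(n: int, sizes) -> int:
    from math import comb
    out, rest = 1, n
    for s in sizes:
        out *= comb(rest, s)
        rest -= s
    return out


# ---------------------------------------------------------------------------
# Grouping-combination optimization
# ---------------------------------------------------------------------------

@dataclass
class GroupingSearchResult:
    table: list[dict]              # ranked by Fct descending
    optimum: Grouping
    optimum_result: AMOVAResult
    pareto_conflict: bool          # Fct-max and Fsc-min disagree


def grouping_search(dataset, candidates, model: str = "differences",
                    n_perm: int = 0, seed: int = 0,
                    fct_tolerance: float = 1e-9) -> GroupingSearchResult:
    """Evaluate candidate population groupings and select the optimum:
    among candidates maximizing Fct (within *fct_tolerance*), the one
    minimizing Fsc. The full ranked table is always returned so users can
    re-rank under a different criterion."""
    candidates = list(candidates)
    if not candidates:
        raise AMOVAError("no candidate groupings supplied")
    popset = candidates[0].populations
    for cand in candidates[1:]:
        if cand.populations != popset:
            raise AMOVAError("candidates must partition the same population set")

    from .popdist import squared_distance_matrix

    records = [r for r in dataset.records if r.population_id in popset]
    pop_order = sorted({r.population_id for r in records})
    pop_to_idx = {p: i for i, p in enumerate(pop_order)}
    idx = np.array([pop_to_idx[r.population_id] for r in records])
    d2 = squared_distance_matrix([r.sequence for r in records], model)
    ps = _PairSums(d2, idx, len(pop_order))

    rows = []
    for cand in candidates:
        gidx = cand.group_index()
        membership = [[] for _ in cand.groups]
        for p, i in pop_to_idx.items():
            membership[gidx[p]].append(i)
        res = _decompose(ps, membership)
        res.grouping = cand
        if n_perm > 0:
            res = amova_permutation(dataset, cand, n_perm=n_perm, seed=seed, model=model)
        rows.append({"grouping": cand, "name": cand.name, "n_groups": len(cand.groups),
                     "fct": res.phi_ct, "fsc": res.phi_sc, "fst": res.phi_st,
                     "p_ct": res.p_ct, "p_sc": res.p_sc, "result": res})

    rows.sort(key=lambda r: (-(r["fct"] if r["fct"] is not None else -np.inf),
                             r["fsc"] if r["fsc"] is not None else np.inf,
                             r["name"]))
    best_fct = rows[0]["fct"]
    near = [r for r in rows if r["fct"] is not None and r["fct"] >= best_fct - fct_tolerance]
    winner = min(near, key=lambda r: (r["fsc"], r["name"]))
    global_min_fsc = min(r["fsc"] for r in rows if r["fsc"] is not None)
    pareto_conflict = winner["fsc"] > global_min_fsc + fct_tolerance
    return GroupingSearchResult(table=rows, optimum=winner["grouping"],
                                optimum_result=winner["result"],
                                pareto_conflict=pareto_conflict)


def enumerate_groupings(populations, fixed_block=(), n_groups: int = 3) -> list[Grouping]:
    """All partitions of the non-fixed populations into at most
    ``n_groups - 1`` non-empty groups, each combined with the fixed block
    as its own group; deterministic canonical ordering."""
    if n_groups < 2:
        raise AMOVAError("n_groups must be >= 2")
    populations = list(populations)
    fixed = [p for p in populations if p in set(fixed_block)]
    if set(fixed_block) - set(populations):
        raise AMOVAError("fixed_block must be a subset of populations")
    free = [p for p in populations if p not in set(fixed_block)]
    out: list[Grouping] = []
    if not free:
        return [Grouping("fixed-only", (tuple(fixed),))]
    seen = set()
    for parts in _set_partitions(free, n_groups - 1):
        groups = tuple(tuple(g) for g in ([fixed] if fixed else []) + parts)
        key = tuple(sorted(tuple(sorted(g)) for g in groups))
        if key not in seen:
            seen.add(key)
            name = " | ".join(",".join(g) for g in groups)
            out.append(Grouping(name, groups))
    return out


def _set_partitions(items, max_groups):
    """Set partitions via restricted-growth strings, canonical order."""
    n = len(items)

    def rec(i, code, k):
        if i == n:
            parts = [[] for _ in range(k)]
            for j, c in enumerate(code):
                parts[c].append(items[j])
            yield parts
            return
        for c in range(min(k + 1, max_groups)):
            nk = k + 1 if c == k else k
            yield from rec(i + 1, code + [c], nk)

    yield from rec(0, [], 0)


def write_search_table(result: GroupingSearchResult, path) -> None:
    import pandas as pd

    rows = [{k: v for k, v in row.items() if k not in ("grouping", "result")}
            for row in result.table]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_amova_manifest(result: AMOVAResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_manifest(), fh, indent=2)
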