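"""Synthetic mtDNA datasets with controllable population structure.

A founder-divergence model, not a coalescent: each truth group carries a
founder haplotype derived from a shared root sequence, every individual is
its population founder plus a Poisson number of private mutations. This is
deliberately the simplest generative process whose within/between variance
the downstream estimators (diversity, PhiST, AMOVA, grouping search) are
meant to resolve; it makes the generating partition, planted duplicate
pairs and first-occurrence epochs exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import EPOCH_ORDER, Region, SampleMetadata, SequenceDataset, SequenceRecord

BASES = "ACGT"

#: Purine/pyrimidine partners used by the transition-biased mutation mode.
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    ``founder_divergence`` is the expected number of fixed differences
    injected on each truth-group founder lineage relative to the shared
    root (two groups are therefore separated by about twice this many
    substitutions, minus rare coincident hits). ``within_theta`` is the
    expected number of private mutations per individual.
    """

    n_populations: int = 3
    n_per_population: int | list[int] = 20
    region_length: int = 337
    founder_divergence: float = 4.0
    within_theta: float = 1.0
    truth_groups: list[list[int]] | None = None  # population indices per group
    epoch_labels: list[str] | None = None
    haplogroup_profile: dict[str, list[float]] | list[dict[str, list[float]]] | None = None
    sex_ratio: float = 0.5
    n_identical_pairs: int = 0
    n_one_diff_pairs: int = 0
    transition_bias: float = 0.0  # 0 = uniform; kappa-style weight toward transitions
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_population, int):
            return [self.n_per_population] * self.n_populations
        return list(self.n_per_population)

    def validate(self) -> None:
        if self.n_populations < 1 or self.region_length < 1:
            raise ValueError("counts must be positive")
        if any(n < 1 for n in self.sizes()):
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0,1]")
        if self.truth_groups is not None:
            flat = sorted(i for g in self.truth_groups for i in g)
            if flat != list(range(self.n_populations)):
                raise ValueError("truth_groups must partition the population indices")
        if self.epoch_labels is not None:
            unknown = set(self.epoch_labels) - set(EPOCH_ORDER)
            if unknown:
                raise ValueError(f"unknown epoch labels: {unknown}")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated dataset."""

    groups: list[list[str]]                       # population ids per truth group
    pair_regime: dict[tuple[str, str], str] = field(default_factory=dict)
    identical_pairs: list[tuple[str, str]] = field(default_factory=list)
    one_diff_pairs: list[tuple[str, str]] = field(default_factory=list)
    first_epoch: dict[str, str] = field(default_factory=dict)  # haplotype -> epoch
    seed: int = 0

    def to_manifest(self) -> dict:
        return {
            "groups": self.groups,
            "identical_pairs": [list(p) for p in self.identical_pairs],
            "one_diff_pairs": [list(p) for p in self.one_diff_pairs],
            "seed": self.seed,
        }


def mutate_sequence(founder: str, k: int, seed: int | np.random.Generator) -> str:
    """Apply exactly *k* substitutions at distinct uniform positions, each
    to a uniformly chosen different base. Deterministic given the seed."""
    if k > len(founder):
        raise ValueError(f"k={k} exceeds sequence length {len(founder)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.choice(len(founder), size=k, replace=False)
    seq = list(founder)
    for pos in positions:
        alts = [b for b in BASES if b != seq[pos]]
        seq[pos] = alts[rng.integers(len(alts))]
    return "".join(seq)


def _mutate_biased(founder: str, k: int, kappa: float, rng: np.random.Generator) -> str:
    """Substitutions with transition weight kappa relative to each
    transversion (exercises the TN93 distance model)."""
    if kappa <= 0:
        return mutate_sequence(founder, k, rng)
    positions = rng.choice(len(founder), size=k, replace=False)
    seq = list(founder)
    for pos in positions:
        ts = _TRANSITION[seq[pos]]
        tv = [b for b in BASES if b != seq[pos] and b != ts]
        weights = np.array([kappa, 1.0, 1.0])
        weights /= weights.sum()
        seq[pos] = [ts, *tv][rng.choice(3, p=weights)]
    return "".join(seq)


def simulate_divergence_populations(config: SimConfig) -> tuple[SequenceDataset, TruthRecord]:
    """Emit a dataset plus its ground truth under the founder model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_populations
    sizes = config.sizes()
    groups = config.truth_groups or [[i] for i in range(P)]
    epochs = config.epoch_labels or ["IA"] * P
    pop_ids = [f"POP{i:02d}" for i in range(P)]
    region = Region(1, config.region_length, "synthetic")

    root = "".join(rng.choice(list(BASES), size=config.region_length))
    group_founders = {}
    for gi, members in enumerate(groups):
        k = rng.poisson(config.founder_divergence)
        k = min(k, config.region_length)
        group_founders[gi] = _mutate_biased(root, k, config.transition_bias, rng)
    founder_of_pop = {}
    for gi, members in enumerate(groups):
        for pi in members:
            founder_of_pop[pi] = group_founders[gi]

    profiles = config.haplogroup_profile
    records: list[SequenceRecord] = []
    metadata: dict[str, SampleMetadata] = {}
    counter = 0
    for pi in range(P):
        for _ in range(sizes[pi]):
            sid = f"S{counter:04d}"
            counter += 1
            k = min(rng.poisson(config.within_theta), config.region_length)
            seq = _mutate_biased(founder_of_pop[pi], k, config.transition_bias, rng)
            records.append(SequenceRecord(sid, pop_ids[pi], seq, region, epochs[pi]))
            metadata[sid] = _draw_metadata(sid, pi, profiles, config.sex_ratio, rng)

    truth = TruthRecord(groups=[[pop_ids[i] for i in g] for g in groups], seed=config.seed)

    # Planted near-duplicates: copies of randomly chosen existing samples.
    base = list(records)
    for kind, n_pairs in (("identical", config.n_identical_pairs),
                          ("one_diff", config.n_one_diff_pairs)):
        for _ in range(n_pairs):
            src = base[rng.integers(len(base))]
            sid = f"S{counter:04d}"
            counter += 1
            seq = src.sequence if kind == "identical" else _mutate_biased(
                src.sequence, 1, config.transition_bias, rng)
            records.append(SequenceRecord(sid, src.population_id, seq, region, src.epoch))
            meta = metadata[src.sample_id]
            metadata[sid] = SampleMetadata(
                sid, meta.anthropological_sex, meta.genetic_sex,
                meta.haplogroup_label, meta.haplogroup_score)
            pair = (src.sample_id, sid)
            (truth.identical_pairs if kind == "identical" else truth.one_diff_pairs).append(pair)

    # Pairwise differentiation regimes implied by the generative parameters.
    group_of = {pop_ids[p]: gi for gi, g in enumerate(groups) for p in g}
    for i, a in enumerate(pop_ids):
        for b in pop_ids[i + 1:]:
            if group_of[a] == group_of[b]:
                truth.pair_regime[(a, b)] = "none"
            else:
                truth.pair_regime[(a, b)] = (
                    "strong" if config.founder_divergence >= 2 * config.within_theta
                    else "weak")

    # First-occurrence epoch per emitted haplotype (earliest epoch of any
    # population containing that exact sequence).
    order = {e: i for i, e in enumerate(EPOCH_ORDER)}
    for rec in records:
        cur = truth.first_epoch.get(rec.sequence)
        if cur is None or order[rec.epoch] < order[cur]:
            truth.first_epoch[rec.sequence] = rec.epoch

    return SequenceDataset(records=records, metadata=metadata), truth


def _draw_metadata(sid: str, pop_index: int, profiles, sex_ratio: float,
                   rng: np.random.Generator) -> SampleMetadata:
    sex = "F" if rng.random() < sex_ratio else "M"
    hap = None
    if profiles is not None:
        profile = profiles[pop_index] if isinstance(profiles, list) else profiles
        labels = list(profile)
        probs = np.asarray([profile[l] for l in labels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("haplogroup profile probabilities must sum to 1")
        hap = labels[rng.choice(len(labels), p=probs)]
    return SampleMetadata(sid, anthropological_sex=sex, genetic_sex=sex,
                          haplogroup_label=hap, haplogroup_score=1.0)


def generate_frequency_profiles(alpha_by_epoch: dict[str, np.ndarray], bins,
                                populations_by_epoch: dict[str, int], seed: int):
    """Draw population haplogroup-frequency rows from per-epoch Dirichlets.

    Returns a pandas-free structure handled by hapfreq.FrequencyMatrix via
    its ``from_frequencies`` constructor; rows sum to 1 by construction.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = {}
    for epoch, n_pops in populations_by_epoch.items():
        alpha = np.asarray(alpha_by_epoch[epoch], dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")
        if alpha.shape != (len(bins),):
            raise ValueError("alpha length must match the bin scheme")
        for i in range(n_pops):
            rows[f"{epoch}{i:02d}"] = rng.dirichlet(alpha)
    return pd.DataFrame(rows, index=list(bins)).T
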