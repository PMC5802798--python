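"""Shared-haplotype analyses: classical sharing fractions and the
epoch-ordered ancestral-lineage assignment.

Haplotype identity is exact string equality over a fully called region:
target haplotypes containing any non-called position (N/-) are excluded
and reported rather than wildcard-matched, because wildcards would
inflate apparent sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import CALLED_BASES, EPOCH_ORDER


class SharedError(ValueError):
    pass


def _distinct_called(haplotypes) -> tuple[list[str], list[str]]:
    """(distinct fully-called haplotypes, excluded partially-called ones)."""
    clean, excluded = [], []
    for h in dict.fromkeys(h.upper() for h in haplotypes):
        (clean if all(c in CALLED_BASES for c in h) else excluded).append(h)
    return clean, excluded


@dataclass
class SharedResult:
    percentage: float                       # distinct-haplotype mode
    percentage_individuals: float           # individuals-weighted mode
    per_reference: dict[str, float]         # reference population -> percent
    n_target_haplotypes: int
    n_excluded_partial: int


def shared_fraction(target_haplotypes, reference_populations: dict[str, list[str]],
                    weights: list[int] | None = None) -> SharedResult:
    """Percentage of distinct target haplotypes found identically in at
    least one reference population, with a per-reference breakdown.

    *weights* (individuals per distinct target haplotype) feeds the
    individuals-weighted percentage reported alongside; both denominators
    are emitted because published sharing figures mix the two conventions.
    """
    targets, excluded = _distinct_called(target_haplotypes)
    if not targets:
        raise SharedError("no fully called target haplotypes")
    refs = {name: set(_distinct_called(haps)[0])
            for name, haps in reference_populations.items()}
    anywhere = set().union(*refs.values()) if refs else set()
    hit = [h in anywhere for h in targets]
    if weights is None:
        weights = [1] * len(targets)
    if len(weights) != len(targets):
        raise SharedError("weights must align with distinct target haplotypes")
    total_w = sum(weights)
    return SharedResult(
        percentage=100.0 * sum(hit) / len(targets),
        percentage_individuals=100.0 * sum(w for w, h in zip(weights, hit) if h) / total_w,
        per_reference={name: 100.0 * sum(h in rset for h in targets) / len(targets)
                       for name, rset in refs.items()},
        n_target_haplotypes=len(targets),
        n_excluded_partial=len(excluded),
    )


@dataclass
class LineageReport:
    assignments: dict[str, tuple[str, list[str]]]  # haplotype -> (epoch|novel, pops)
    incidence: dict[str, float] = field(default_factory=dict)  # epoch/novel -> percent
    incidence_individuals: dict[str, float] = field(default_factory=dict)
    n_target_haplotypes: int = 0
    n_excluded_partial: int = 0


def ancestral_assign(target_haplotypes,
                     reference_populations: dict[str, tuple[str, list[str]]],
                     weights: list[int] | None = None) -> LineageReport:
    """Assign each distinct target haplotype to the EARLIEST epoch whose
    reference populations contain it identically; unmatched haplotypes are
    "novel". *reference_populations* maps population name ->
    (epoch label, haplotype list). Incidences are percentages over distinct
    target haplotypes (and, alongside, over individuals)."""
    order = {e: i for i, e in enumerate(EPOCH_ORDER)}
    for name, (epoch, _) in reference_populations.items():
        if epoch not in order:
            raise SharedError(f"reference {name}: unknown epoch {epoch!r}")
    targets, excluded = _distinct_called(target_haplotypes)
    if not targets:
        raise SharedError("no fully called target haplotypes")
    refs = {name: (epoch, set(_distinct_called(haps)[0]))
            for name, (epoch, haps) in reference_populations.items()}

    assignments: dict[str, tuple[str, list[str]]] = {}
    for h in targets:
        matches = [(order[epoch], epoch, name)
                   for name, (epoch, hapset) in refs.items() if h in hapset]
        if not matches:
            assignments[h] = ("novel", [])
        else:
            earliest = min(m[0] for m in matches)
            pops = sorted(name for o, _, name in matches if o == earliest)
            epoch = next(e for o, e, _ in matches if o == earliest)
            assignments[h] = (epoch, pops)

    if weights is None:
        weights = [1] * len(targets)
    total_w = sum(weights)
    incidence: dict[str, float] = {}
    incidence_w: dict[str, float] = {}
    for h, w in zip(targets, weights):
        epoch = assignments[h][0]
        incidence[epoch] = incidence.get(epoch, 0.0) + 100.0 / len(targets)
        incidence_w[epoch] = incidence_w.get(epoch, 0.0) + 100.0 * w / total_w
    return LineageReport(assignments, incidence, incidence_w,
                         n_target_haplotypes=len(targets),
                         n_excluded_partial=len(excluded))
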