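"""Sex-stratified re-analysis: split the target population into female and
male subgroups by consensus sex and re-run the population-level analyses
on each, plus a Fisher R x C test of the F-vs-M haplogroup bin counts.

Individuals of unknown sex are excluded from both subgroups but remain in
the pooled analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import diversity, hapfreq, popdist
from .seqio import SequenceDataset, resolve_sex


@dataclass
class StratifiedResult:
    subgroups: dict[str, list[str]]              # F / M / unassigned -> sample ids
    diversity: dict[str, dict] = field(default_factory=dict)
    frequency: "pd.DataFrame | None" = None      # bins x (F, M, unassigned, pooled)
    fisher_p: float | None = None
    fisher_table: "pd.DataFrame | None" = None
    fst_to_references: dict[str, "pd.Series"] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def split_by_sex(dataset: SequenceDataset, population: str) -> dict[str, list[str]]:
    out = {"F": [], "M": [], "unassigned": []}
    for rec in dataset.population(population):
        meta = dataset.metadata[rec.sample_id]
        sex, _ = resolve_sex(meta.anthropological_sex, meta.genetic_sex)
        out[sex if sex in ("F", "M") else "unassigned"].append(rec.sample_id)
    return out


def stratify_and_run(dataset: SequenceDataset, population: str,
                     scheme: hapfreq.BinScheme = hapfreq.CEPT23,
                     model: str = "differences", n_sim: int = 10000,
                     seed: int = 0) -> StratifiedResult:
    """Run diversity, haplogroup-frequency and Fst-to-reference analyses on
    the F and M subgroups of *population* (other populations in the dataset
    act as references), and test F-vs-M bin counts with Fisher's R x C."""
    subgroups = split_by_sex(dataset, population)
    result = StratifiedResult(subgroups=subgroups)
    references = [p for p in dataset.populations if p != population]

    freq_cols: dict[str, pd.Series] = {}
    for sex in ("F", "M", "unassigned"):
        ids = subgroups[sex]
        assignments = {
            sid: (sex, dataset.metadata[sid].haplogroup_label)
            for sid in ids if dataset.metadata[sid].haplogroup_label
        }
        if assignments:
            fm = hapfreq.build_frequency_matrix(assignments, scheme)
            freq_cols[sex] = fm.counts.loc[sex]
        else:
            freq_cols[sex] = pd.Series(0, index=list(scheme.bins))
        if len(ids) < 2:
            result.skipped[sex] = "fewer than 2 members; sequence analyses skipped"
            continue
        seqs = [r.sequence for r in dataset.records if r.sample_id in set(ids)]
        result.diversity[sex] = {
            "hd": diversity.haplotype_diversity(seqs),
            "pi": diversity.nucleotide_diversity(seqs),
        }
        if references:
            sub = dataset.subset(
                ids + [r.sample_id for r in dataset.records
                       if r.population_id != population])
            renamed = SequenceDataset(
                records=[r if r.population_id != population
                         else type(r)(r.sample_id, f"{population}-{sex}",
                                      r.sequence, r.region, r.epoch)
                         for r in sub.records],
                metadata=dict(sub.metadata))
            try:
                fst = popdist.pairwise_phist(renamed, model=model)
                row = fst.to_frame().loc[f"{population}-{sex}", references]
                result.fst_to_references[sex] = row
            except popdist.DistanceError as exc:
                result.skipped[sex] = f"Fst skipped: {exc}"

    pooled = freq_cols["F"] + freq_cols["M"] + freq_cols["unassigned"]
    result.frequency = pd.DataFrame(
        {**freq_cols, "pooled": pooled}).astype(int)

    table = pd.DataFrame({"F": freq_cols["F"], "M": freq_cols["M"]}).T
    table = table.loc[:, table.sum(axis=0) > 0]  # drop empty bins
    if table.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
        result.fisher_table = table
        result.fisher_p = hapfreq.fisher_rxc(table.to_numpy(), n_sim=n_sim, seed=seed)
    else:
        warnings.warn("F-vs-M table degenerate; Fisher test skipped", stacklevel=2)
    return result
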