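"""End-to-end orchestration: run the full study workflow from one config.

Stages run in the order the analysis is designed: read/filter -> duplicate
removal -> diversity -> MSN -> haplogroup frequencies -> Fst/MDS ->
AMOVA grouping search -> shared haplotypes -> sex stratification. Every
stage receives a seed derived from the master seed by a counter scheme
(seed * 1000 + stage index, mod 2^31), so any stage can be re-run in
isolation reproducibly; each output directory carries a JSON manifest
with input checksums, parameters and the stage seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import amova, diversity, hapfreq, network, popdist, sexdiff, shared as shared_mod
from . import seqio

log = logging.getLogger("mtstruct")

STAGES = ("filter", "dedup", "diversity", "msn", "hapfreq", "fst",
          "amova", "shared", "sexdiff")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    fasta: str
    metadata: str | None = None
    target_population: str | None = None
    region: tuple[int, int] = (1, 16569)
    hd_regions: list[tuple[int, int]] = field(default_factory=lambda: [(16033, 16365), (73, 340)])
    pi_region: tuple[int, int] = (16000, 16410)
    fst_region: tuple[int, int] = (16064, 16400)
    bin_scheme: str = "CEPT23"
    distance_model: str = "differences"
    gamma_shape: float | None = None
    min_score: float = 0.0
    min_coverage: float = 0.0
    exclusion_list: list[str] = field(default_factory=list)
    n_permutations: int = 999
    n_bootstrap: int = 1000
    grouping_file: str | None = None
    deduplicate: bool = True
    seed: int = 0
    outdir: str = "mtstruct_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for name in ("fasta", "metadata", "grouping_file"):
            value = getattr(cfg, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGES.index(stage)) % (2 ** 31)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, config: RunConfig, **params) -> None:
    inputs = {}
    for p in (config.fasta, config.metadata, config.grouping_file):
        if p is not None and Path(p).exists():
            inputs[str(p)] = _checksum(p)
    payload = {"stage": stage, "seed": config.stage_seed(stage),
               "inputs_sha256": inputs, "parameters": params}
    with open(outdir / f"{stage}_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a summary dict mirroring the report
    bundle written under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}
    region = seqio.Region(*config.region)

    def announce(stage):
        log.info("stage=%s seed=%d", stage, config.stage_seed(stage))
        summary["stages"].append(stage)

    try:
        stage = "filter"
        announce(stage)
        records = seqio.read_fasta(config.fasta, region)
        metadata = seqio.read_metadata(config.metadata) if config.metadata else {}
        dataset = seqio.SequenceDataset(records=records, metadata={
            **{r.sample_id: seqio.SampleMetadata(r.sample_id) for r in records},
            **metadata})
        if metadata:
            kept, dropped = seqio.filter_assignments(
                metadata, config.min_score, config.min_coverage, config.exclusion_list)
            seqio.write_filter_report(kept, dropped, outdir / "filter_report.json")
            summary["n_kept"] = len(kept)
        _manifest(outdir, stage, config, min_score=config.min_score,
                  min_coverage=config.min_coverage)

        target = config.target_population or dataset.populations[0]

        stage = "dedup"
        announce(stage)
        if config.deduplicate:
            dataset, removals = network.deduplicate(dataset)
            with open(outdir / "dedup_log.json", "w") as fh:
                json.dump(removals, fh, indent=2)
            summary["n_removed_duplicates"] = len(removals)
        _manifest(outdir, stage, config, enabled=config.deduplicate)

        stage = "diversity"
        announce(stage)
        target_records = dataset.population(target)
        hd_regions = [seqio.Region(a, b) for a, b in config.hd_regions]
        div = {}
        if len(target_records) >= 2:
            try:
                hd_haps = [seqio.concat_regions(r, hd_regions).sequence
                           for r in target_records]
            except seqio.SeqIOError:
                hd_haps = [r.sequence for r in target_records]
            hd = diversity.haplotype_diversity(hd_haps)
            try:
                pi_seqs = [seqio.slice_region(r, seqio.Region(*config.pi_region)).sequence
                           for r in target_records]
            except seqio.SeqIOError:
                pi_seqs = [r.sequence for r in target_records]
            pi = diversity.nucleotide_diversity(pi_seqs)
            div = {"hd": hd.estimate, "hd_sd": hd.standard_deviation,
                   "pi": pi.estimate, "pi_sd": pi.standard_deviation, "n": hd.n}
            with open(outdir / "diversity.json", "w") as fh:
                json.dump(div, fh, indent=2)
        summary["diversity"] = div
        _manifest(outdir, stage, config, hd_regions=config.hd_regions,
                  pi_region=config.pi_region)

        stage = "msn"
        announce(stage)
        nodes = network.collapse_haplotypes(target_records or dataset.records)
        msn = network.build_msn(nodes)
        msn.write_edgelist(outdir / "msn_edges.tsv")
        msn.write_memberships(outdir / "msn_members.tsv")
        summary["msn_nodes"] = len(nodes)
        summary["msn_edges"] = len(msn.edges)
        _manifest(outdir, stage, config)

        stage = "hapfreq"
        announce(stage)
        scheme = hapfreq.SCHEMES[config.bin_scheme]
        assignments = {
            r.sample_id: (r.population_id, dataset.metadata[r.sample_id].haplogroup_label)
            for r in dataset.records
            if dataset.metadata[r.sample_id].haplogroup_label}
        freq = None
        if assignments:
            freq = hapfreq.build_frequency_matrix(assignments, scheme)
            freq.write_tsv(outdir / "haplogroup_counts.tsv")
            if len(freq.populations) >= 2:
                dendro = hapfreq.bootstrap_support(
                    freq, n_boot=config.n_bootstrap, seed=config.stage_seed(stage))
                with open(outdir / "ward_support.json", "w") as fh:
                    json.dump({" | ".join(sorted(c)): s
                               for c, s in dendro.support.items()}, fh, indent=2)
                pca = hapfreq.pca_frequencies(freq)
                pca.write(outdir)
                summary["pca_pc12_percent"] = float(
                    100 * pca.explained_fraction[:2].sum())
        _manifest(outdir, stage, config, scheme=config.bin_scheme,
                  n_bootstrap=config.n_bootstrap)

        stage = "fst"
        announce(stage)
        try:
            fst_dataset = dataset.restrict(seqio.Region(*config.fst_region))
        except seqio.SeqIOError:
            fst_dataset = dataset
        if len(fst_dataset.populations) >= 2:
            fst = popdist.compute_fst(
                fst_dataset, model=config.distance_model,
                n_perm=config.n_permutations, seed=config.stage_seed(stage),
                gamma_shape=config.gamma_shape)
            fst.write(outdir / "fst")
            coords, stress = popdist.mds_embed(fst.linearized, mode="nonmetric",
                                               seed=config.stage_seed(stage))
            import pandas as pd
            pd.DataFrame(coords, index=fst.fst.labels,
                         columns=["MDS1", "MDS2"]).to_csv(outdir / "mds.tsv", sep="\t")
            summary["mds_stress"] = stress
        _manifest(outdir, stage, config, model=config.distance_model,
                  n_permutations=config.n_permutations)

        stage = "amova"
        announce(stage)
        if config.grouping_file:
            candidates = amova.read_groupings(config.grouping_file)
            search = amova.grouping_search(
                fst_dataset if len(fst_dataset.populations) >= 2 else dataset,
                candidates, model=config.distance_model)
            amova.write_search_table(search, outdir / "grouping_search.tsv")
            best = amova.amova_permutation(
                fst_dataset, search.optimum, n_perm=config.n_permutations,
                seed=config.stage_seed(stage), model=config.distance_model)
            amova.write_amova_manifest(best, outdir / "amova_optimum.json")
            summary["optimal_grouping"] = search.optimum.name
            summary["fct"] = best.phi_ct
            summary["fsc"] = best.phi_sc
        else:
            log.info("stage=amova skipped (no grouping file)")
            summary["stages"].append("amova:skipped")
        _manifest(outdir, stage, config, grouping_file=config.grouping_file)

        stage = "shared"
        announce(stage)
        refs = {p: (dataset.population(p)[0].epoch,
                    [r.sequence for r in dataset.population(p)])
                for p in dataset.populations if p != target}
        if refs and target_records:
            report = shared_mod.ancestral_assign(
                [r.sequence for r in target_records], refs)
            with open(outdir / "lineages.json", "w") as fh:
                json.dump({"incidence": report.incidence,
                           "incidence_individuals": report.incidence_individuals},
                          fh, indent=2)
            summary["lineage_incidence"] = report.incidence
        _manifest(outdir, stage, config)

        stage = "sexdiff"
        announce(stage)
        if len(dataset.population(target)) >= 4:
            strat = sexdiff.stratify_and_run(
                dataset, target, scheme=scheme, model=config.distance_model,
                n_sim=max(config.n_permutations, 999),
                seed=config.stage_seed(stage))
            strat.frequency.to_csv(outdir / "sex_frequency.tsv", sep="\t")
            summary["fisher_f_vs_m_p"] = strat.fisher_p
            summary["subgroup_sizes"] = {k: len(v) for k, v in strat.subgroups.items()}
        _manifest(outdir, stage, config)

    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        report = {"failed_stage": stage, "error": str(exc),
                  "type": type(exc).__name__}
        with open(outdir / "error_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise PipelineError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
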