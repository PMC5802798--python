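"""Input/output and sample-level filtering for rCRS-aligned mtDNA data.

All coordinates are 1-based inclusive rCRS nucleotide positions ("np"),
the convention used throughout human mtDNA work. Sequences are stored on
the rCRS plus strand as uppercase strings over {A, C, G, T, N, -}; both
"N" (missing base) and "-" (alignment gap) count as non-called positions
for every downstream distance computation.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RCRS_LENGTH = 16569

#: Chronological ordering of the epoch labels used by the lineage analyses:
#: hunter-gatherers, Early/Middle Neolithic, Late Neolithic / Early Bronze
#: Age, Iron Age, and present-day reference panels.
EPOCH_ORDER = ("HG", "EN", "MN", "LN/EBA", "IA", "present")

VALID_SEX = ("F", "M", "unknown")

CALLED_BASES = frozenset("ACGT")


class SeqIOError(ValueError):
    """Raised on malformed input files or coordinate violations."""


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive slice of the rCRS coordinate system."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise SeqIOError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise SeqIOError(f"region end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Region") -> bool:
        return self.start <= other.start and other.end <= self.end

    def __str__(self) -> str:  # "16064:16400" style, used by the CLI
        return f"{self.start}:{self.end}"


# Canonical regions of the hypervariable control-region segments used by
# the analyses: HD uses HVS-I 16033-16365 and HVS-II 73-340, nucleotide
# diversity uses 16000-16410, Fst uses 16064-16400.
HVS1_HD = Region(16033, 16365, "HVS-I")
HVS2_HD = Region(73, 340, "HVS-II")
HVS1_PI = Region(16000, 16410, "HVS-I-pi")
HVS1_FST = Region(16064, 16400, "HVS-I-fst")


@dataclass(frozen=True)
class SequenceRecord:
    sample_id: str
    population_id: str
    sequence: str
    region: Region
    epoch: str = "IA"

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region.length:
            raise SeqIOError(
                f"{self.sample_id}: sequence length {len(self.sequence)} != "
                f"region length {self.region.length}"
            )

    def called_mask(self) -> list[bool]:
        return [c in CALLED_BASES for c in self.sequence]


@dataclass
class SampleMetadata:
    sample_id: str
    anthropological_sex: str = "unknown"
    genetic_sex: str = "unknown"
    haplogroup_label: str | None = None
    haplogroup_score: float | None = None
    mean_coverage: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.haplogroup_score is not None and not 0.0 <= self.haplogroup_score <= 1.0:
            raise SeqIOError(
                f"{self.sample_id}: haplogroup score {self.haplogroup_score} not in [0,1]"
            )
        for sex in (self.anthropological_sex, self.genetic_sex):
            if sex not in VALID_SEX:
                raise SeqIOError(f"{self.sample_id}: invalid sex code {sex!r}")
        if self.excluded and not self.exclusion_reason:
            raise SeqIOError(f"{self.sample_id}: excluded flag requires a reason")


@dataclass
class SequenceDataset:
    records: list[SequenceRecord] = field(default_factory=list)
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        region = None
        for rec in self.records:
            if rec.sample_id in seen:
                raise SeqIOError(f"duplicate sample id {rec.sample_id}")
            seen.add(rec.sample_id)
            if region is None:
                region = rec.region
            elif rec.region != region:
                raise SeqIOError(
                    f"{rec.sample_id}: region {rec.region} differs from dataset region {region}"
                )
            self.metadata.setdefault(rec.sample_id, SampleMetadata(rec.sample_id))

    @property
    def region(self) -> Region | None:
        return self.records[0].region if self.records else None

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.population_id not in out:
                out.append(rec.population_id)
        return out

    def population(self, population_id: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.population_id == population_id]

    def subset(self, sample_ids) -> "SequenceDataset":
        keep = set(sample_ids)
        return SequenceDataset(
            records=[r for r in self.records if r.sample_id in keep],
            metadata={k: v for k, v in self.metadata.items() if k in keep},
        )

    def restrict(self, region: Region) -> "SequenceDataset":
        return SequenceDataset(
            records=[slice_region(r, region) for r in self.records],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, region: Region, default_population: str = "POP",
               default_epoch: str = "IA") -> list[SequenceRecord]:
    """Read rCRS-aligned sequences, slicing full-length genomes to *region*.

    Headers follow the ``sampleid|population`` convention (optionally
    ``sampleid|population|epoch``); a bare header assigns
    *default_population*. Each sequence must be exactly region length or
    full rCRS length (16569), in which case it is sliced.
    """
    records: list[SequenceRecord] = []
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        parts = bio.id.split("|")
        sample_id = parts[0]
        population = parts[1] if len(parts) > 1 and parts[1] else default_population
        epoch = parts[2] if len(parts) > 2 and parts[2] else default_epoch
        seq = str(bio.seq).upper()
        if len(seq) == region.length:
            pass
        elif len(seq) == RCRS_LENGTH:
            seq = seq[region.start - 1: region.end]
        else:
            raise SeqIOError(
                f"record {bio.id!r}: length {len(seq)} is neither region length "
                f"{region.length} nor rCRS length {RCRS_LENGTH}"
            )
        records.append(SequenceRecord(sample_id, population, seq, region, epoch))
    return records


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=f"{r.sample_id}|{r.population_id}|{r.epoch}",
                      description="")
        for r in records
    ]
    _BioSeqIO.write(bio, str(path), "fasta")


def slice_region(record: SequenceRecord, region: Region) -> SequenceRecord:
    """Extract a sub-record by 1-based inclusive rCRS coordinates."""
    if not record.region.contains(region):
        raise SeqIOError(
            f"{record.sample_id}: requested region {region} outside record "
            f"region {record.region}"
        )
    offset = region.start - record.region.start
    return replace(record, sequence=record.sequence[offset: offset + region.length],
                   region=region)


def concat_regions(record: SequenceRecord, regions) -> SequenceRecord:
    """Joint haplotype over several regions (e.g. HVS-I + HVS-II).

    Regions are concatenated in ascending coordinate order; the synthetic
    region spans them with the combined length (coordinates of the joint
    record are only meaningful through its parts).
    """
    parts = sorted(regions, key=lambda r: r.start)
    for a, b in zip(parts, parts[1:]):
        if b.start <= a.end:
            raise SeqIOError(f"overlapping regions {a} and {b}")
    seq = "".join(slice_region(record, r).sequence for r in parts)
    label = "+".join(str(r) for r in parts)
    joint = Region(parts[0].start, parts[0].start + len(seq) - 1, label)
    return replace(record, sequence=seq, region=joint)


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def parse_sex_token(token: str) -> tuple[str, str]:
    """Parse the ``(F)/M`` notation: anthropological in parentheses,
    genetic after the slash; ``-`` means unassigned."""
    token = token.strip()
    anthro, _, genetic = token.partition("/")
    anthro = anthro.strip("()").strip()
    genetic = genetic.strip()
    norm = lambda s: s if s in ("F", "M") else "unknown"
    return norm(anthro), norm(genetic)


def _clean(value) -> str | None:
    s = str(value).strip()
    if s in ("", "-", "−", "—", "nan", "None"):
        return None
    return s


def read_metadata(path) -> dict[str, SampleMetadata]:
    """Read the tab-separated assignment table (Table-1 dialect).

    Columns: sample_id, haplogroup_score, haplogroup, then either a single
    ``sex`` column in ``(F)/M`` notation or separate
    ``anthropological_sex``/``genetic_sex`` columns; optional
    ``mean_coverage``. Decimal commas in scores are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        score = _clean(row.get("haplogroup_score"))
        if score is not None:
            score = float(score.replace(",", "."))
        hap = _clean(row.get("haplogroup"))
        if hap is not None:
            hap = hap.rstrip("*")
        if "sex" in df.columns:
            anthro, genetic = parse_sex_token(str(row["sex"]))
        else:
            anthro = _clean(row.get("anthropological_sex")) or "unknown"
            genetic = _clean(row.get("genetic_sex")) or "unknown"
        cov = _clean(row.get("mean_coverage"))
        out[sid] = SampleMetadata(
            sample_id=sid,
            anthropological_sex=anthro if anthro in ("F", "M") else "unknown",
            genetic_sex=genetic if genetic in ("F", "M") else "unknown",
            haplogroup_label=hap,
            haplogroup_score=score,
            mean_coverage=float(cov) if cov is not None else None,
        )
    return out


def write_metadata(metadata: dict[str, SampleMetadata], path) -> None:
    rows = []
    for m in metadata.values():
        rows.append({
            "sample_id": m.sample_id,
            "haplogroup_score": "-" if m.haplogroup_score is None else m.haplogroup_score,
            "haplogroup": m.haplogroup_label or "-",
            "anthropological_sex": m.anthropological_sex.replace("unknown", "-"),
            "genetic_sex": m.genetic_sex.replace("unknown", "-"),
            "mean_coverage": "-" if m.mean_coverage is None else m.mean_coverage,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_kowalewko_assignments() -> dict[str, SampleMetadata]:
    """The packaged transcription of the published assignment table for the
    60 Kowalewko (Kow-OVIA) individuals."""
    ref = importlib.resources.files("mtstruct.data") / "kowalewko_assignments.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_metadata(path)


def read_haplogroup_counts(path) -> pd.DataFrame:
    """Population x haplogroup count table (TSV, first column = population)."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Filtering and sex resolution
# ---------------------------------------------------------------------------

def filter_assignments(metadata: dict[str, SampleMetadata], min_score: float = 0.0,
                       min_coverage: float = 0.0, exclusion_list=()) \
        -> tuple[dict[str, SampleMetadata], dict[str, str]]:
    """Apply the sample-level filters used before every downstream analysis.

    Keeps samples that carry a haplogroup label, meet the score and coverage
    thresholds (``>=``, missing values fail a positive threshold), and are
    not on the explicit exclusion list (e.g. contamination-flagged
    individuals). Returns (kept, dropped-with-reason).
    """
    if min_score < 0 or min_coverage < 0:
        raise SeqIOError("thresholds must be non-negative")
    excluded = set(exclusion_list)
    kept: dict[str, SampleMetadata] = {}
    dropped: dict[str, str] = {}
    for sid, meta in metadata.items():
        if sid in excluded:
            dropped[sid] = "on exclusion list"
        elif meta.haplogroup_label is None:
            dropped[sid] = "no haplogroup assignment"
        elif min_score > 0 and (meta.haplogroup_score is None
                                or meta.haplogroup_score < min_score):
            dropped[sid] = f"haplogroup score below {min_score}"
        elif min_coverage > 0 and (meta.mean_coverage is None
                                   or meta.mean_coverage < min_coverage):
            dropped[sid] = f"coverage below {min_coverage}"
        else:
            kept[sid] = meta
    return kept, dropped


def resolve_sex(anthropological_sex: str, genetic_sex: str) -> tuple[str, bool]:
    """Consensus sex: molecular assignment takes precedence over the
    anthropological one; a disagreement keeps the genetic call and raises
    the conflict flag."""
    for sex in (anthropological_sex, genetic_sex):
        if sex not in VALID_SEX:
            raise SeqIOError(f"invalid sex code {sex!r}")
    if genetic_sex != "unknown":
        conflict = anthropological_sex != "unknown" and anthropological_sex != genetic_sex
        return genetic_sex, conflict
    return anthropological_sex, False


def write_filter_report(kept, dropped, path) -> None:
    report = {
        "n_input": len(kept) + len(dropped),
        "n_kept": len(kept),
        "kept": sorted(kept),
        "dropped": {k: dropped[k] for k in sorted(dropped)},
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
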