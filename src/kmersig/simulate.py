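"""Synthetic two-class RNA-seq cohorts with planted differential sequences.

The generator emulates the situation the discovery pipeline targets: two
labelled groups of bulk RNA-seq samples sharing a background transcriptome,
plus a few *planted events* — sequences whose expression differs between
the groups by a chosen fold change.  Three event kinds cover the classes
of reference-free biomarkers seen in practice:

* ``novel_transcript`` — a transcript absent from any reference (e.g. an
  unannotated lncRNA), expressed in both groups but scaled by the fold
  change in the positive group;
* ``snv_variant`` — a background transcript carrying a single-nucleotide
  variant, so only the k-mers overlapping the variant discriminate;
* ``retained_intron`` — a background transcript with an extra internal
  segment (an unspliced intron), discriminating via intron and junction
  k-mers.

Per-sample transcript abundances follow a negative-binomial (gamma-Poisson)
model: baseline weights are multiplied by per-sample gamma noise with
dispersion ``dispersion`` (default 0.2, a typical bulk RNA-seq value), and
reads are drawn multinomially, uniformly along transcripts, with random
strand.  The background is random sequence at GC 0.5 — adequate for
exercising k-mer logic, but free of the repeats, homopolymers and GC bias
of real transcriptomes.  No sequencing errors are simulated by default
(``error_rate=0``): errors only add spurious low-count k-mers that the
recurrence filter removes.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kmersig.io import write_fastq
from kmersig.kmers import count_codes
from kmersig.preprocess import CohortLabels, NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_BYTE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_BYTE[_a] = _b


@dataclass(frozen=True)
class PlantedEvent:
    """A sequence enriched ``fold_change``-fold in the positive group.

    ``base_expression`` is the event transcript's baseline weight relative
    to the mean background transcript weight (1.0 = an average transcript).
    """

    kind: str
    fold_change: float = 8.0
    base_expression: float = 1.0
    length: int = 500  # novel transcript length / intron length uses 150

    def __post_init__(self) -> None:
        if self.kind not in ("novel_transcript", "snv_variant", "retained_intron"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.base_expression <= 0:
            raise ValueError("base_expression must be > 0")


def default_events() -> tuple[PlantedEvent, ...]:
    return (
        PlantedEvent("novel_transcript", fold_change=8.0),
        PlantedEvent("snv_variant", fold_change=8.0),
        PlantedEvent("retained_intron", fold_change=8.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of a synthetic cohort; ``seed`` is mandatory."""

    seed: int
    cohort_seed: int | None = None  # draw a second cohort from the same world
    n_background_transcripts: int = 200
    transcript_length_range: tuple[int, int] = (500, 1500)
    n_samples_per_class: int = 40
    reads_per_sample: int = 100_000
    read_length: int = 100
    paired: bool = False
    events: tuple[PlantedEvent, ...] = field(default_factory=default_events)
    dispersion: float = 0.2
    error_rate: float = 0.0
    intron_length: int = 150
    k: int = 31  # used to derive event truth k-mers

    def __post_init__(self) -> None:
        if self.n_background_transcripts < 1 or self.n_samples_per_class < 1:
            raise ValueError("counts must be positive")
        if self.reads_per_sample < 1 or self.read_length < 1:
            raise ValueError("reads_per_sample and read_length must be positive")
        if self.dispersion < 0 or not (0 <= self.error_rate < 1):
            raise ValueError("invalid dispersion or error_rate")
        span = 2 * self.read_length if self.paired else self.read_length
        if span > self.transcript_length_range[0]:
            raise ValueError(
                "read (or fragment) length exceeds the shortest transcript; "
                "reads would not fit"
            )


@dataclass
class TruthTable:
    """Planted events: sequence, direction, fold change, member k-mers."""

    table: pd.DataFrame  # index event_id; columns kind, sequence, direction, fold_change
    member_kmers: dict[str, set]  # event_id -> set of canonical k-mer codes
    k: int

    def event_ids(self) -> list[str]:
        return list(self.table.index)

    def events_hit(self, sequences: dict[str, str]) -> dict[str, set]:
        """Which planted events share a k-mer with each given sequence.

        ``sequences`` maps ids (e.g. signature contig ids) to DNA strings;
        returns {sequence id -> set of event ids hit}.
        """
        hits: dict[str, set] = {}
        for name, seq in sequences.items():
            codes, _ = count_codes([seq], self.k)
            code_set = set(codes.tolist())
            hit = {
                eid for eid, members in self.member_kmers.items() if members & code_set
            }
            if hit:
                hits[name] = hit
        return hits

    def recovered_events(self, sequences: dict[str, str]) -> set:
        found = set()
        for hit in self.events_hit(sequences).values():
            found |= hit
        return found

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "event_id"
        out.to_csv(path, sep="\t")


@dataclass
class SyntheticCohort:
    """Generated reads per sample plus labels and ground truth.

    Reads are held as (n_reads, read_length) uint8 byte matrices — the
    counting module consumes these directly; :meth:`write_fastq` exports
    standard FASTQ.gz files with a sample sheet.
    """

    config: SimulationConfig
    reads: dict[str, np.ndarray]
    labels: CohortLabels
    truth: TruthTable

    @property
    def sample_ids(self) -> list[str]:
        return list(self.reads)

    def reads_as_strings(self, sample_id: str) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.reads[sample_id]]

    def write_fastq(self, outdir, gzip_output: bool = True) -> Path:
        """Write FASTQ(.gz) per sample, sample sheet, labels and truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        rows = []
        for sid in self.sample_ids:
            path = outdir / f"{sid}{suffix}"
            write_fastq(path, self.reads_as_strings(sid), name_prefix=sid)
            rows.append({"sample_id": sid, "fastq1": str(path)})
        pd.DataFrame(rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        lab = self.labels.labels.rename_axis("sample_id").reset_index()
        lab.to_csv(outdir / "labels.tsv", sep="\t", index=False)
        self.truth.to_tsv(outdir / "truth.tsv")
        return outdir


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_seq_bytes(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_BYTES[rng.integers(0, 4, size=length)]


def _bytes_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP_BYTE[arr][::-1]


def _build_transcriptome(config: SimulationConfig, rng: np.random.Generator):
    """Background + event transcripts, event truth sequences and k-mers."""
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_background_transcripts)
    background = [_random_seq_bytes(rng, int(L)) for L in lengths]
    bg_codes, _ = count_codes(
        [_bytes_to_str(t) for t in background], config.k
    )
    bg_set = set(bg_codes.tolist())

    k = config.k
    transcripts = list(background)
    weights_extra = []  # (transcript index, base_expression, fold_change)
    truth_rows = []
    member_kmers: dict[str, set] = {}

    host_pool = rng.permutation(config.n_background_transcripts)
    host_i = 0
    for e_idx, ev in enumerate(config.events):
        eid = f"event_{e_idx + 1}_{ev.kind}"
        for _attempt in range(20):
            if ev.kind == "novel_transcript":
                seq = _random_seq_bytes(rng, ev.length)
                truth_seq = seq
                new_transcript = seq
            elif ev.kind == "snv_variant":
                host = background[host_pool[host_i % len(host_pool)]]
                mid = len(host) // 2
                new_transcript = host.copy()
                alternatives = [b for b in _BASE_BYTES if b != host[mid]]
                new_transcript[mid] = alternatives[rng.integers(0, 3)]
                truth_seq = new_transcript[max(0, mid - k + 1): mid + k]
            else:  # retained_intron
                host = background[host_pool[host_i % len(host_pool)]]
                mid = len(host) // 2
                intron = _random_seq_bytes(rng, config.intron_length)
                new_transcript = np.concatenate([host[:mid], intron, host[mid:]])
                truth_seq = np.concatenate(
                    [host[mid - k + 1: mid], intron, host[mid: mid + k - 1]]
                )
            codes, _ = count_codes([_bytes_to_str(truth_seq)], k)
            code_set = set(codes.tolist())
            if code_set and not (code_set & bg_set):
                break
        else:
            raise RuntimeError(f"could not plant event {eid} without background collision")
        if ev.kind != "novel_transcript":
            host_i += 1
        transcripts.append(new_transcript)
        weights_extra.append((len(transcripts) - 1, ev))
        member_kmers[eid] = code_set
        truth_rows.append(
            {
                "event_id": eid,
                "kind": ev.kind,
                "sequence": _bytes_to_str(truth_seq),
                "direction": "positive" if ev.fold_change >= 1 else "negative",
                "fold_change": ev.fold_change,
            }
        )

    truth = TruthTable(
        table=pd.DataFrame(truth_rows).set_index("event_id"),
        member_kmers=member_kmers,
        k=k,
    )
    return transcripts, weights_extra, truth


def _sample_reads(
    big: np.ndarray,
    offsets: np.ndarray,
    lengths: np.ndarray,
    probs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one sample's reads as an (n_reads, read_length) byte matrix.

    Paired mode draws fragments of 2 x read_length and emits both mates
    (mate 2 reverse-complemented), so total sequenced bases match the
    single-end mode; mates are independent reads to the counter.
    """
    rl = config.read_length
    span = 2 * rl if config.paired else rl
    n_units = config.reads_per_sample // 2 if config.paired else config.reads_per_sample
    counts = rng.multinomial(n_units, probs)
    starts = np.empty(n_units, dtype=np.int64)
    pos = 0
    for t, c in enumerate(counts):
        if c == 0:
            continue
        n_start = max(lengths[t] - span + 1, 1)
        starts[pos: pos + c] = offsets[t] + rng.integers(0, n_start, size=c)
        pos += c
    idx = starts[:, None] + np.arange(rl)[None, :]
    reads = big[idx]
    if config.paired:
        mate2 = big[starts[:, None] + np.arange(rl, 2 * rl)[None, :]]
        mate2 = _COMP_BYTE[mate2][:, ::-1]
        reads = np.concatenate([reads, mate2], axis=0)
    n_reads = reads.shape[0]
    flip = rng.random(n_reads) < 0.5
    reads[flip] = _COMP_BYTE[reads[flip]][:, ::-1]
    if config.error_rate > 0:
        err = rng.random(reads.shape) < config.error_rate
        reads[err] = _BASE_BYTES[
            (
                np.searchsorted(_BASE_BYTES, reads[err]) + rng.integers(1, 4, err.sum())
            ) % 4
        ]
    return reads


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a labelled two-class cohort under ``config``.

    Positive samples express each planted event ``fold_change`` times its
    baseline; everything else differs only by negative-binomial noise.

    ``config.seed`` fixes the *world* (transcriptome, planted events,
    baseline weights); ``config.cohort_seed``, when given, draws an
    independent cohort of samples from that same world — the way to build
    a matched validation cohort.
    """
    rng = np.random.default_rng(config.seed)
    transcripts, weights_extra, truth = _build_transcriptome(config, rng)

    lengths = np.array([len(t) for t in transcripts], dtype=np.int64)
    if config.read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest transcript")
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    big = np.concatenate(transcripts)

    n_bg = config.n_background_transcripts
    base_weights = np.empty(len(transcripts))
    base_weights[:n_bg] = rng.lognormal(mean=0.0, sigma=1.0, size=n_bg)
    mean_bg = base_weights[:n_bg].mean()
    fold = np.ones(len(transcripts))
    for t_idx, ev in weights_extra:
        base_weights[t_idx] = ev.base_expression * mean_bg
        fold[t_idx] = ev.fold_change

    if config.cohort_seed is not None:
        rng = np.random.default_rng(config.cohort_seed)

    reads: dict[str, np.ndarray] = {}
    label_map = {}
    shape = 1.0 / config.dispersion if config.dispersion > 0 else None
    n_eff = np.maximum(lengths - config.read_length + 1, 1)
    for cls, prefix, factor in ((NEGATIVE, "neg", np.ones_like(fold)), (POSITIVE, "pos", fold)):
        for i in range(config.n_samples_per_class):
            sid = f"{prefix}_{i + 1:03d}"
            noise = (
                rng.gamma(shape, scale=config.dispersion, size=len(transcripts))
                if shape is not None
                else np.ones(len(transcripts))
            )
            w = base_weights * factor * noise * n_eff
            probs = w / w.sum()
            reads[sid] = _sample_reads(big, offsets, lengths, probs, config, rng)
            label_map[sid] = cls
    labels = CohortLabels(
        labels=pd.Series(label_map, name="label"), task="simulated",
        rule_set=f"synthetic[seed={config.seed}]",
    )
    logger.info(
        "simulated cohort: 2x%d samples, %d reads/sample, %d transcripts, %d events",
        config.n_samples_per_class, config.reads_per_sample,
        len(transcripts), len(config.events),
    )
    return SyntheticCohort(config=config, reads=reads, labels=labels, truth=truth)


def downsample_cohort(cohort: SyntheticCohort, fraction: float, seed: int) -> SyntheticCohort:
    """Keep each read independently with probability ``fraction``.

    Emulates a low-coverage validation cohort; deterministic under ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    new_reads = {}
    for sid in cohort.sample_ids:
        mat = cohort.reads[sid]
        keep = rng.random(mat.shape[0]) < fraction
        new_reads[sid] = mat[keep]
    return SyntheticCohort(
        config=cohort.config, reads=new_reads, labels=cohort.labels, truth=cohort.truth
    )
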