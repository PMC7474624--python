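"""Strain quantification from shotgun reads of a defined community.

The stage mirrors how defined-consortium metagenomes are profiled: reads are
quality-trimmed, subsampled to a fixed depth (default 100,000) so samples are
comparable, classified against the strain-unique k-mer index, and the raw
counts are scaled by each strain's informative length ``U_i`` (or, in the
literal alternative, by whole-genome length ``L_i``) before renormalizing to
relative abundance. Scaling by ``U_i`` removes the bias that longer or more
unique genomes attract more reads per cell, so relative abundances estimate
cell proportions under uniform coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kmers as km
from .errors import InconsistencyError, InputError
from .reference import UniqueRegionIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "AbundanceTable",
    "trim_reads",
    "subsample_reads",
    "classify_reads",
    "scale_abundance",
    "call_presence",
    "absolute_abundance",
    "quantify_sample",
    "read_fastq",
    "write_fastq",
]

DEFAULT_SUBSAMPLE = 100_000
DEFAULT_MIN_HITS = 3
DEFAULT_MIN_RELATIVE = 1e-4
DEFAULT_MIN_READS = 5


@dataclass
class ReadSet:
    """Sequencing reads: (id, sequence, optional quality string) triples."""

    reads: list[tuple[str, str, str | None]]

    def __post_init__(self) -> None:
        for rid, seq, qual in self.reads:
            if not seq:
                raise InputError(f"read {rid!r} has empty sequence")
            if qual is not None and len(qual) != len(seq):
                raise InputError(f"read {rid!r} quality length mismatch")

    @property
    def n(self) -> int:
        return len(self.reads)


@dataclass
class AbundanceTable:
    """Samples x strains abundance matrix with raw counts and metadata.

    ``counts`` are integer classified-read counts per strain; ``unassigned``
    is the per-sample remainder (counts + unassigned = subsampled depth).
    ``abundance`` rows sum to 1 over strains with nonzero counts; an all-zero
    sample keeps a zero row and is listed in ``meta['all_zero_samples']``.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    abundance: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        long = self.abundance.stack().rename("relative_abundance").reset_index()
        long.columns = ["sample_id", "strain_id", "relative_abundance"]
        cnt = self.counts.stack().rename("count").reset_index(drop=True)
        long["count"] = cnt
        return long


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33


def trim_reads(reads: ReadSet, quality_threshold: int = 20, min_length: int = 31) -> ReadSet:
    """3'-trim low-quality tails and drop reads shorter than ``min_length``.

    Bases are removed from the 3' end while their Phred quality is below the
    threshold. Reads without qualities pass through unchanged (warned when a
    nonzero threshold was requested). Conservation: kept + dropped = input.
    """
    if quality_threshold < 0 or min_length < 0:
        raise InputError("thresholds must be nonnegative")
    kept: list[tuple[str, str, str | None]] = []
    dropped = trimmed = missing_qual = 0
    for rid, seq, qual in reads.reads:
        if qual is None:
            missing_qual += 1
            if len(seq) >= min_length:
                kept.append((rid, seq, qual))
            else:
                dropped += 1
            continue
        q = _phred(qual)
        end = len(seq)
        while end > 0 and q[end - 1] < quality_threshold:
            end -= 1
        if end < len(seq):
            trimmed += 1
        if end >= min_length:
            kept.append((rid, seq[:end], qual[:end]))
        else:
            dropped += 1
    if missing_qual and quality_threshold > 0:
        logger.warning("%d reads lack qualities; passed through untrimmed", missing_qual)
    logger.info("trim: kept=%d trimmed=%d dropped=%d", len(kept), trimmed, dropped)
    out = ReadSet(kept)
    out.trim_log = {"kept": len(kept), "trimmed": trimmed, "dropped": dropped}  # type: ignore[attr-defined]
    return out


def subsample_reads(reads: ReadSet, n: int = DEFAULT_SUBSAMPLE, seed: int = 0) -> ReadSet:
    """Draw exactly min(n, |reads|) reads uniformly without replacement.

    Output preserves input order (order-stable), is deterministic given the
    seed, and passes everything through with a warning when fewer than ``n``
    reads are available.
    """
    if n < 1:
        raise InputError("subsample size must be >= 1")
    if reads.n <= n:
        if reads.n < n:
            logger.warning("only %d reads available for subsample of %d; keeping all", reads.n, n)
        return ReadSet(list(reads.reads))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(reads.n, size=n, replace=False))
    return ReadSet([reads.reads[i] for i in idx])


def _classify_packed(reads: ReadSet, index: UniqueRegionIndex, min_hits: int):
    k = index.k
    seqs = [seq for _, seq, _ in reads.reads]
    # concatenate with single-N separators: any window spanning two reads
    # contains the N and is invalid
    big = "N".join(seqs)
    canon, valid = km.canonical_kmers(big, k)
    offsets = np.cumsum([0] + [len(s) + 1 for s in seqs])  # start of each read in big
    n_strains = len(index.strain_ids)
    counts_mat = np.zeros((reads.n, n_strains), dtype=np.int32)
    if canon.size:
        owners = index.lookup_packed(canon)
        hit = valid & (owners >= 0)
        if hit.any():
            pos = np.flatnonzero(hit)
            read_idx = np.searchsorted(offsets, pos, side="right") - 1
            np.add.at(counts_mat, (read_idx, owners[pos]), 1)
    return counts_mat


def classify_reads(reads: ReadSet, index: UniqueRegionIndex, min_hits: int = DEFAULT_MIN_HITS
                   ) -> tuple[pd.Series, int]:
    """Assign each read to the strain owning most of its unique k-mers.

    A read is assigned to the single strain with the maximal number of
    strain-unique canonical k-mer hits, provided hits >= ``min_hits`` and no
    tie; otherwise it is unassigned (ties across strains can only arise
    through sequencing error, by construction of the index). Reads shorter
    than k are unassigned. Conservation: sum(counts) + unassigned = |reads|.
    """
    if min_hits < 1:
        raise InputError("min_hits must be >= 1")
    n_strains = len(index.strain_ids)
    if reads.n == 0:
        return pd.Series(0, index=index.strain_ids, name="count", dtype=int), 0
    if index.k <= 31 and index._sorted_kmers is not None:
        counts_mat = _classify_packed(reads, index, min_hits)
    else:
        counts_mat = np.zeros((reads.n, n_strains), dtype=np.int32)
        for ri, (_, seq, _) in enumerate(reads.reads):
            for p in range(len(seq) - index.k + 1):
                w = seq[p : p + index.k]
                if "N" in w:
                    continue
                owner = index.lookup_string(min(w, km.revcomp(w)))
                if owner >= 0:
                    counts_mat[ri, owner] += 1
    best = counts_mat.max(axis=1)
    n_best = (counts_mat == best[:, None]).sum(axis=1)
    assigned_mask = (best >= min_hits) & (n_best == 1)
    winners = counts_mat.argmax(axis=1)
    c = np.bincount(winners[assigned_mask], minlength=n_strains)
    counts = pd.Series(c, index=index.strain_ids, name="count", dtype=int)
    unassigned = int(reads.n - assigned_mask.sum())
    short = sum(1 for _, seq, _ in reads.reads if len(seq) < index.k)
    if short:
        logger.info("%d reads shorter than k=%d counted unassigned", short, index.k)
    return counts, unassigned


def scale_abundance(counts: pd.Series, index: UniqueRegionIndex, mode: str = "informative") -> pd.Series:
    """Scale raw counts to relative abundance.

    ``mode='informative'`` (default) divides each strain's count by its
    informative length ``U_i`` — the number of positions a read can map to —
    recovering cell-proportional composition under uniform coverage.
    ``mode='genome'`` divides by whole-genome length ``L_i``.
    """
    if mode not in ("informative", "genome"):
        raise InputError(f"unknown scaling mode {mode!r}")
    denom = index.informative_lengths if mode == "informative" else index.lengths
    dens = {}
    for sid in index.strain_ids:
        c = int(counts.get(sid, 0))
        d = denom[sid]
        if c > 0 and index.informative_lengths[sid] == 0:
            raise InconsistencyError(f"strain {sid!r} has reads but zero informative length")
        dens[sid] = c / d if d > 0 else 0.0
    total = sum(dens.values())
    if total == 0:
        return pd.Series({sid: 0.0 for sid in index.strain_ids}, name="relative_abundance")
    return pd.Series({sid: v / total for sid, v in dens.items()}, name="relative_abundance")


def call_presence(abundance: AbundanceTable, min_relative: float = DEFAULT_MIN_RELATIVE,
                  min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Presence matrix: strain present iff a_i >= min_relative and c_i >= min_reads."""
    if min_relative < 0 or min_reads < 0:
        raise InputError("thresholds must be nonnegative")
    return (abundance.abundance >= min_relative) & (abundance.counts >= min_reads)


def absolute_abundance(abundance: AbundanceTable, density: pd.Series) -> pd.DataFrame:
    """Per-strain absolute abundance: relative abundance x microbiota density.

    ``density`` maps sample id to fecal DNA density (ng/mg); row sums of the
    result equal the sample's density. Missing densities are an error.
    """
    missing = set(abundance.abundance.index) - set(density.index)
    if missing:
        raise InputError(f"no density for samples {sorted(missing)!r}")
    return abundance.abundance.mul(density.reindex(abundance.abundance.index), axis=0)


def quantify_sample(reads: ReadSet, index: UniqueRegionIndex, *,
                    sample_id: str = "sample",
                    subsample_n: int = DEFAULT_SUBSAMPLE,
                    seed: int = 0,
                    quality_threshold: int = 20,
                    min_length: int | None = None,
                    min_hits: int = DEFAULT_MIN_HITS,
                    mode: str = "informative") -> AbundanceTable:
    """Full per-sample quantification: trim, subsample, classify, scale.

    Returns a one-row :class:`AbundanceTable`; all parameters are echoed in
    ``meta``.
    """
    min_length = index.k if min_length is None else min_length
    trimmed = trim_reads(reads, quality_threshold, min_length)
    sub = subsample_reads(trimmed, subsample_n, seed)
    counts, unassigned = classify_reads(sub, index, min_hits)
    rel = scale_abundance(counts, index, mode)
    meta = {
        "seed": seed, "subsample_n": subsample_n, "subsampled": sub.n,
        "quality_threshold": quality_threshold, "min_length": min_length,
        "min_hits": min_hits, "mode": mode, "k": index.k,
        "all_zero_samples": [sample_id] if counts.sum() == 0 else [],
    }
    return AbundanceTable(
        counts=pd.DataFrame([counts.rename(sample_id)]),
        unassigned=pd.Series({sample_id: unassigned}, name="unassigned"),
        abundance=pd.DataFrame([rel.rename(sample_id)]),
        meta=meta,
    )


def combine_tables(tables: list[AbundanceTable]) -> AbundanceTable:
    """Stack per-sample tables into one multi-sample table."""
    if not tables:
        raise InputError("no tables to combine")
    return AbundanceTable(
        counts=pd.concat([t.counts for t in tables]),
        unassigned=pd.concat([t.unassigned for t in tables]),
        abundance=pd.concat([t.abundance for t in tables]),
        meta={"per_sample": [t.meta for t in tables],
              "all_zero_samples": sum((t.meta.get("all_zero_samples", []) for t in tables), [])},
    )


def read_fastq(path) -> ReadSet:
    """Load reads from a (plain-text) FASTQ file."""
    reads: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # separator
            qual = fh.readline().strip()
            reads.append((header.strip()[1:].split()[0], seq, qual or None))
    return ReadSet(reads)


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual if qual is not None else 'I' * len(seq)}\n")
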