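"""Strain-unique region index over a defined consortium of genomes.

In a gnotobiotic experiment every organism that can occur in a sample is known,
so reads can be attributed to strains through genome regions whose k-mers occur
in exactly one genome of that closed universe. This module builds that index:
for each strain, the set of strain-unique canonical k-mers, the maximal
intervals of unique k-mer start positions, and the informative length
``U_i`` (number of unique k-mer positions) used to normalize read counts.

Uniqueness is defined at the whole-universe level: a canonical k-mer is unique
to strain *i* iff it occurs in no other genome of the universe, on either
strand, regardless of its copy number within genome *i* (a multi-copy marker
still identifies the strain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import kmers as km
from .errors import InputError

__all__ = [
    "StrainGenome",
    "UniqueRegionIndex",
    "build_unique_index",
    "export_unique_regions",
    "load_unique_regions",
    "read_genomes_fasta",
    "write_genomes_fasta",
]

_VALID_ALPHABET = set("ACGTN")


@dataclass
class StrainGenome:
    """A consortium member's genome: id, sequence and length ``L_i``."""

    strain_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError(f"genome {self.strain_id!r} is empty")
        extra = set(self.sequence) - _VALID_ALPHABET
        if extra:
            raise InputError(f"genome {self.strain_id!r} has invalid characters {sorted(extra)!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class UniqueRegionIndex:
    """Per-strain unique k-mer content of a genome universe.

    ``intervals`` are 0-based half-open runs of strain-unique k-mer *start*
    positions, so interval lengths per strain sum to ``U_i``.
    """

    k: int
    strain_ids: list[str]
    lengths: dict[str, int]
    informative_lengths: dict[str, int]
    intervals: dict[str, list[tuple[int, int]]]
    # classifier lookup structures (packed path, k <= 31)
    _sorted_kmers: np.ndarray | None = field(default=None, repr=False)
    _owners: np.ndarray | None = field(default=None, repr=False)
    # string fallback, k > 31
    _kmer_dict: dict | None = field(default=None, repr=False)

    def unique_kmer_set(self, strain_id: str) -> set:
        """The strain's unique canonical k-mers (packed ints, or strings for k > 31)."""
        i = self.strain_ids.index(strain_id)
        if self._sorted_kmers is not None:
            return set(self._sorted_kmers[self._owners == i].tolist())
        return {kmer for kmer, owner in self._kmer_dict.items() if owner == i}

    def lookup_packed(self, canon: np.ndarray) -> np.ndarray:
        """Owner strain index for each packed canonical k-mer, -1 if not unique to any."""
        if self._sorted_kmers is None:
            raise InputError("packed lookup unavailable for this index (k > 31)")
        pos = np.searchsorted(self._sorted_kmers, canon)
        pos = np.minimum(pos, len(self._sorted_kmers) - 1) if len(self._sorted_kmers) else pos
        out = np.full(len(canon), -1, dtype=np.int32)
        if len(self._sorted_kmers):
            hit = self._sorted_kmers[pos] == canon
            out[hit] = self._owners[pos[hit]]
        return out

    def lookup_string(self, canon_kmer: str) -> int:
        if self._kmer_dict is not None:
            return self._kmer_dict.get(canon_kmer, -1)
        code, valid = km.canonical_kmers(canon_kmer, self.k)
        if not valid[0]:
            return -1
        return int(self.lookup_packed(code[:1])[0])


def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def build_unique_index(genomes: list[StrainGenome], k: int = 31) -> UniqueRegionIndex:
    """Build the strain-unique canonical k-mer index over a genome universe.

    A position's canonical k-mer is strain-unique iff it occurs in exactly one
    genome of the universe (either strand; any copy number inside that genome).
    Windows containing N are excluded. Genomes shorter than k contribute no
    unique content (warned, not fatal).
    """
    if k % 2 == 0 or not 15 <= k <= 63:
        raise InputError("k must be odd and in [15, 63]")
    ids = [g.strain_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate strain_id in genome universe")
    if not genomes:
        raise InputError("empty genome universe")

    lengths = {g.strain_id: g.length for g in genomes}
    packed = k <= 31

    if packed:
        per_genome = []  # (canon, valid) per genome
        for g in genomes:
            per_genome.append(km.canonical_kmers(g.sequence, k))
        # count, per canonical k-mer, the number of distinct genomes containing it
        sets = []
        for canon, valid in per_genome:
            sets.append(np.unique(canon[valid]))
        if sets and any(s.size for s in sets):
            allk = np.concatenate([s for s in sets if s.size])
            uniq, counts = np.unique(allk, return_counts=True)
            singly = uniq[counts == 1]
        else:
            singly = np.empty(0, dtype=np.uint64)
        # owner of each singly-occurring k-mer
        owners = np.full(len(singly), -1, dtype=np.int32)
        for i, s in enumerate(sets):
            pos = np.searchsorted(singly, s)
            pos = np.clip(pos, 0, max(len(singly) - 1, 0))
            if len(singly):
                hit = singly[pos] == s
                owners[pos[hit]] = i
        informative, intervals = {}, {}
        for i, g in enumerate(genomes):
            canon, valid = per_genome[i]
            if canon.size == 0:
                informative[g.strain_id] = 0
                intervals[g.strain_id] = []
                continue
            pos = np.searchsorted(singly, canon)
            pos = np.clip(pos, 0, max(len(singly) - 1, 0))
            is_unique = valid.copy()
            if len(singly):
                is_unique &= singly[pos] == canon
                is_unique &= owners[pos] == i
            else:
                is_unique[:] = False
            informative[g.strain_id] = int(is_unique.sum())
            intervals[g.strain_id] = _intervals_from_mask(is_unique)
        return UniqueRegionIndex(k, ids, lengths, informative, intervals,
                                 _sorted_kmers=singly, _owners=owners)

    # string fallback for k > 31
    genome_count: dict[str, int] = {}
    per_pos: list[list[str | None]] = []
    for g in genomes:
        seen = set()
        row: list[str | None] = []
        n = g.length - k + 1
        for p in range(max(n, 0)):
            w = g.sequence[p : p + k]
            if "N" in w:
                row.append(None)
                continue
            c = min(w, km.revcomp(w))
            row.append(c)
            seen.add(c)
        per_pos.append(row)
        for c in seen:
            genome_count[c] = genome_count.get(c, 0) + 1
    kmer_dict: dict[str, int] = {}
    informative, intervals = {}, {}
    for i, g in enumerate(genomes):
        mask = np.zeros(len(per_pos[i]), dtype=bool)
        for p, c in enumerate(per_pos[i]):
            if c is not None and genome_count[c] == 1:
                mask[p] = True
                kmer_dict[c] = i
        informative[g.strain_id] = int(mask.sum())
        intervals[g.strain_id] = _intervals_from_mask(mask)
    return UniqueRegionIndex(k, ids, lengths, informative, intervals, _kmer_dict=kmer_dict)


def export_unique_regions(index: UniqueRegionIndex, genomes: list[StrainGenome],
                          bed_path, masked_fasta_path, manifest_path) -> None:
    """Write the index as BED intervals, a hard-masked FASTA and a JSON manifest.

    BED intervals are 0-based half-open over unique k-mer start positions. The
    masked FASTA keeps only bases covered by at least one strain-unique k-mer
    window (everything else becomes N). The manifest records k, L_i and U_i and
    round-trips through :func:`load_unique_regions`.
    """
    by_id = {g.strain_id: g for g in genomes}
    if set(index.strain_ids) - set(by_id):
        raise InputError("genomes missing for some indexed strains")
    k = index.k
    with open(bed_path, "w") as bed:
        for sid in index.strain_ids:
            for start, end in index.intervals[sid]:
                bed.write(f"{sid}\t{start}\t{end}\n")
    records = []
    for sid in index.strain_ids:
        g = by_id[sid]
        keep = np.zeros(g.length, dtype=bool)
        for start, end in index.intervals[sid]:
            keep[start : end + k - 1] = True
        seq = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8).copy()
        seq[~keep] = ord("N")
        records.append(SeqRecord(Seq(seq.tobytes().decode("ascii")), id=sid, description="unique-region masked"))
    SeqIO.write(records, masked_fasta_path, "fasta")
    manifest = {
        "k": k,
        "strains": [
            {"strain_id": sid, "length": index.lengths[sid], "informative_length": index.informative_lengths[sid]}
            for sid in index.strain_ids
        ],
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def load_unique_regions(bed_path, manifest_path) -> UniqueRegionIndex:
    """Re-import a BED + manifest pair; reproduces U_i exactly.

    The returned index carries intervals and informative lengths but no k-mer
    lookup structures (classification needs the full index built from FASTA).
    """
    manifest = json.loads(Path(manifest_path).read_text())
    ids = [s["strain_id"] for s in manifest["strains"]]
    lengths = {s["strain_id"]: s["length"] for s in manifest["strains"]}
    intervals: dict[str, list[tuple[int, int]]] = {sid: [] for sid in ids}
    with open(bed_path) as bed:
        for line in bed:
            if not line.strip():
                continue
            sid, start, end = line.split("\t")[:3]
            intervals[sid].append((int(start), int(end)))
    informative = {sid: sum(e - s for s, e in iv) for sid, iv in intervals.items()}
    declared = {s["strain_id"]: s["informative_length"] for s in manifest["strains"]}
    if informative != declared:
        raise InputError("BED interval lengths disagree with manifest informative lengths")
    return UniqueRegionIndex(manifest["k"], ids, lengths, informative, intervals)


def read_genomes_fasta(path) -> list[StrainGenome]:
    """Load consortium genomes from FASTA; record ids become strain ids."""
    genomes = [StrainGenome(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not genomes:
        raise InputError(f"no FASTA records in {path}")
    return genomes


def write_genomes_fasta(genomes: list[StrainGenome], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.sequence), id=g.strain_id, description="") for g in genomes],
        str(path), "fasta",
    )
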