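"""Synthetic study generator: genomes, reads, phenotypes, density records.

Every downstream stage of the pipeline is exercised against data with known
ground truth. The generators emulate the statistical structure the analyses
assume — multi-strain genomes with controlled shared sequence, shotgun reads
drawn from a known cell-proportion mixture (read counts weighted by genome
length, since reads measure DNA rather than cells), per-mouse immune
phenotypes with planted per-strain causal effects plus Gaussian noise, and
paired pre/post fecal DNA densities with a lognormal group shift after
transplant. All generators are pure functions of their arguments including
the seed, and each returns a truth object recording the planted answer key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .quant import ReadSet
from .reference import StrainGenome

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "simulate_genomes",
    "simulate_reads",
    "simulate_phenotypes",
    "simulate_density",
    "simulate_transplant_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Planted answer key for a synthetic dataset."""

    seed: int
    composition: dict[str, float] = field(default_factory=dict)
    causal_effects: dict[str, float] = field(default_factory=dict)
    density_truth: dict[str, float] = field(default_factory=dict)
    read_sources: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.composition:
            vals = np.array(list(self.composition.values()))
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise InputError("composition must be nonnegative and sum to 1")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_genomes(n_strains: int, length: int, shared_fraction: float = 0.0,
                     n_shared_blocks: int = 1, seed: int = 0, *,
                     kmer_size: int = 31) -> list[StrainGenome]:
    """Random genomes with a controlled fraction of sequence shared by all strains.

    Each genome is i.i.d. random over {A,C,G,T} except for ``shared_fraction``
    of its length, made of ``n_shared_blocks`` common blocks generated once and
    inserted at random positions into every genome (so shared content occurs in
    >= 2 genomes whenever there are >= 2 strains). Deterministic given seed.
    At the lengths used (tens of kb versus 4^k possible k-mers) accidental
    k-mer sharing between the non-block segments is vanishingly unlikely.
    """
    if n_strains < 1:
        raise InputError("need at least one strain")
    if not 0.0 <= shared_fraction < 1.0:
        raise InputError("shared_fraction must be in [0, 1)")
    if length < 10 * kmer_size:
        raise InputError(f"genome length must be >= 10*k = {10 * kmer_size}")
    if shared_fraction > 0 and n_strains < 2:
        raise InputError("shared sequence requires >= 2 strains")
    rng = np.random.default_rng(seed)
    shared_total = int(round(shared_fraction * length))
    if shared_total > 0:
        if n_shared_blocks < 1:
            raise InputError("n_shared_blocks must be >= 1 when shared_fraction > 0")
        sizes = np.full(n_shared_blocks, shared_total // n_shared_blocks)
        sizes[: shared_total % n_shared_blocks] += 1
        sizes = sizes[sizes > 0]
        if sizes.min() < kmer_size:
            raise InputError("shared blocks shorter than k; reduce n_shared_blocks")
        blocks = [_random_seq(rng, s) for s in sizes]
    else:
        blocks = []
    genomes = []
    for i in range(n_strains):
        backbone = _random_seq(rng, length - shared_total)
        if blocks:
            cuts = np.sort(rng.integers(0, len(backbone) + 1, size=len(blocks)))
            parts = []
            prev = 0
            for cut, block in zip(cuts, blocks):
                parts.append(backbone[prev:cut])
                parts.append(block)
                prev = cut
            parts.append(backbone[prev:])
            seq = np.concatenate(parts)
        else:
            seq = backbone
        genomes.append(StrainGenome(f"strain{i + 1:02d}", seq.tobytes().decode("ascii")))
    return genomes


def simulate_reads(genomes: list[StrainGenome], composition: dict[str, float],
                   n_reads: int, read_length: int = 150, error_rate: float = 0.0,
                   seed: int = 0) -> tuple[ReadSet, SyntheticTruth]:
    """Shotgun reads from a known cell-proportion mixture.

    The probability a read originates from strain i is proportional to
    ``composition_i * L_i`` (reads sample DNA mass, not cells; the
    quantifier's informative-length scaling must undo this bias). Start
    positions are uniform, strands equiprobable, and substitutions occur
    per-base at ``error_rate``. Quality strings are constant 'I' (Phred 40).
    """
    by_id = {g.strain_id: g for g in genomes}
    unknown = set(composition) - set(by_id)
    if unknown:
        raise InputError(f"composition references unknown strains {sorted(unknown)!r}")
    if not 0.0 <= error_rate < 0.25:
        raise InputError("error_rate must be in [0, 0.25)")
    ids = [sid for sid in composition if composition[sid] > 0]
    if not ids:
        raise InputError("composition is empty")
    for sid in ids:
        if read_length > by_id[sid].length:
            raise InputError(f"read_length exceeds genome length of {sid!r}")
    rng = np.random.default_rng(seed)
    w = np.array([composition[sid] * by_id[sid].length for sid in ids], dtype=float)
    w /= w.sum()
    src = rng.choice(len(ids), size=n_reads, p=w)
    encoded = {sid: np.frombuffer(by_id[sid].sequence.encode("ascii"), dtype=np.uint8) for sid in ids}
    mat = np.empty((n_reads, read_length), dtype=np.uint8)
    window = np.arange(read_length)
    for si, sid in enumerate(ids):
        m = np.flatnonzero(src == si)
        if m.size == 0:
            continue
        g = encoded[sid]
        starts = rng.integers(0, len(g) - read_length + 1, size=m.size)
        mat[m] = g[starts[:, None] + window]
    # reverse-complement half the reads (strands equiprobable)
    comp_lut = np.arange(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp_lut[a] = b
    flip = rng.random(n_reads) < 0.5
    mat[flip] = comp_lut[mat[flip]][:, ::-1]
    if error_rate > 0:
        emask = rng.random(mat.shape) < error_rate
        ne = int(emask.sum())
        if ne:
            # substitute with a uniformly random *different* base
            shift = rng.integers(1, 4, size=ne)
            codes = np.searchsorted(_BASES, mat[emask])
            mat[emask] = _BASES[(codes + shift) % 4]
    raw = mat.tobytes()
    qual = "I" * read_length
    reads = [(f"r{i:07d}", raw[i * read_length : (i + 1) * read_length].decode("ascii"), qual)
             for i in range(n_reads)]
    sources = [ids[s] for s in src]
    truth_comp = {sid: composition.get(sid, 0.0) for sid in by_id}
    total = sum(truth_comp.values())
    truth = SyntheticTruth(
        seed=seed,
        composition={sid: v / total for sid, v in truth_comp.items()},
        read_sources=pd.Series(sources, index=[r[0] for r in reads], name="source_strain"),
        extras={"error_rate": error_rate, "read_length": read_length},
    )
    return ReadSet(reads), truth


def simulate_phenotypes(design, causal_effects: dict[str, float], baseline: float = 10.0,
                        sigma: float = 2.0, mice_per_group: int = 5, seed: int = 0,
                        *, percentage: bool = True) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-mouse phenotype values over a colonization design.

    ``design`` is a communities x strains binary incidence DataFrame (or a
    presence table with the same shape). Each mouse in community g gets
    ``baseline + sum_s effect_s * X[g, s] + Normal(0, sigma^2)``, clipped to
    [0, 100] when the phenotype is a percentage (clipping is logged).
    """
    X = design.X if hasattr(design, "X") else design
    if not isinstance(X, pd.DataFrame):
        raise InputError("design must be a DataFrame or DesignMatrix")
    unknown = set(causal_effects) - set(X.columns)
    if unknown:
        raise InputError(f"causal effect references unknown strains {sorted(unknown)!r}")
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    if mice_per_group < 1:
        raise InputError("mice_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    effects = pd.Series(0.0, index=X.columns)
    for sid, e in causal_effects.items():
        effects[sid] = e
    rows = []
    n_clipped = 0
    for comm in X.index:
        mu = baseline + float(X.loc[comm] @ effects)
        vals = mu + sigma * rng.standard_normal(mice_per_group)
        if percentage:
            clipped = np.clip(vals, 0.0, 100.0)
            n_clipped += int((clipped != vals).sum())
            vals = clipped
        for m, v in enumerate(vals):
            rows.append({"mouse_id": f"{comm}_m{m + 1}", "community_id": comm,
                         "phenotype": "phenotype_pct", "value": float(v)})
    if n_clipped:
        logger.info("clipped %d phenotype values to [0, 100]", n_clipped)
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(seed=seed, causal_effects=dict(causal_effects),
                           extras={"baseline": baseline, "sigma": sigma,
                                   "mice_per_group": mice_per_group, "n_clipped": n_clipped})
    return table, truth


def simulate_density(n_pre: int, n_post: int, pre_mean: float = 5.0, post_shift: float = 0.0,
                     cv: float = 0.3, seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Paired pre/post fecal DNA density records with a lognormal model.

    Log-density is mouse-baseline plus residual, each carrying half the
    variance implied by ``cv``, so pre and post measurements of the same mouse
    are positively correlated and the paired test gains power. The post-
    transplant arithmetic mean is ``pre_mean + post_shift``. The first
    ``min(n_pre, n_post)`` mice are paired. Fecal masses are uniform 30-80 mg
    and DNA mass is density x mass, so density = dna_mass / fecal_mass exactly.
    """
    if pre_mean <= 0 or pre_mean + post_shift <= 0:
        raise InputError("density means must be > 0")
    if cv <= 0:
        raise InputError("cv must be > 0")
    if n_pre < 1 or n_post < 1:
        raise InputError("need at least one mouse per timepoint")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    s_between = np.sqrt(sigma2 / 2.0)
    s_within = np.sqrt(sigma2 / 2.0)
    n_mice = max(n_pre, n_post)
    b = s_between * rng.standard_normal(n_mice)

    def draw(mean: float, idx: np.ndarray) -> np.ndarray:
        mu = np.log(mean) - sigma2 / 2.0
        return np.exp(mu + b[idx] + s_within * rng.standard_normal(len(idx)))

    rows = []
    truth_density: dict[str, float] = {}
    pre_vals = draw(pre_mean, np.arange(n_pre))
    post_vals = draw(pre_mean + post_shift, np.arange(n_post))
    for tp, vals in (("pre", pre_vals), ("post", post_vals)):
        masses = rng.uniform(30.0, 80.0, size=len(vals))
        for m, (d, fm) in enumerate(zip(vals, masses)):
            sample = f"mouse{m + 1:02d}_{tp}"
            rows.append({"sample_id": sample, "mouse_id": f"mouse{m + 1:02d}", "timepoint": tp,
                         "dna_mass_ng": float(d * fm), "fecal_mass_mg": float(fm),
                         "density_ng_per_mg": float(d)})
            truth_density[sample] = float(d)
    truth = SyntheticTruth(seed=seed, density_truth=truth_density,
                           extras={"pre_mean": pre_mean, "post_shift": post_shift, "cv": cv})
    return pd.DataFrame(rows), truth


#: study-condition consortium sizes: five healthy-donor (HD) consortia spanning
#: 9-22 strains (mean 15.6) and three IBD recipient consortia of 17, 13 and 20
HD_CONSORTIUM_SIZES = {"HD1": 9, "HD2": 13, "HD3": 16, "HD4": 18, "HD5": 22}
IBD_CONSORTIUM_SIZES = {"IBD_A": 17, "IBD_B": 13, "IBD_C": 20}
MEAN_ENGRAFTMENT = 0.593
MEAN_PERSISTENCE = 0.580


def default_study_membership() -> pd.DataFrame:
    """Synthetic consortium membership table at the study's panel structure.

    A stand-in for a strain-list table of a defined-microbiota-transplant
    panel: five healthy-donor (HD) consortia between 9 and 22 strains (mean
    15.6) in the donor role and three IBD-derived consortia of 17, 13 and 20
    strains in the recipient role. Strain ids are synthetic labels.
    """
    rows = []
    for name, size in HD_CONSORTIUM_SIZES.items():
        for i in range(size):
            rows.append({"strain_id": f"{name}_s{i + 1:02d}", "consortium": name,
                         "role": "donor"})
    for name, size in IBD_CONSORTIUM_SIZES.items():
        for i in range(size):
            rows.append({"strain_id": f"{name}_s{i + 1:02d}", "consortium": name,
                         "role": "recipient"})
    return pd.DataFrame(rows)


def simulate_transplant_cohort(recipient_sizes: dict[str, int], donor_sizes: dict[str, int],
                               mice_per_pair: int = 3, engraft_p: float = 0.593,
                               persist_p: float = 0.580, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Presence-level transplant cohort: every recipient x donor combination.

    Each mouse starts colonized with its full recipient consortium; after
    transplant each donor strain engrafts independently with probability
    ``engraft_p`` and each recipient strain persists with probability
    ``persist_p``. Returns (presence, metadata, consortia): a presence matrix
    indexed by (mouse, timepoint) over the union strain universe, per-mouse
    metadata, and the name -> strain-set map.
    """
    if not 0 <= engraft_p <= 1 or not 0 <= persist_p <= 1:
        raise InputError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    consortia = {}
    for name, size in {**recipient_sizes, **donor_sizes}.items():
        consortia[name] = {f"{name}_s{i + 1:02d}" for i in range(size)}
    universe = sorted(set().union(*consortia.values()))
    pres_rows, meta_rows = [], []
    for rec in recipient_sizes:
        for don in donor_sizes:
            for m in range(mice_per_pair):
                mouse = f"{rec}x{don}_m{m + 1}"
                meta_rows.append({"mouse_id": mouse, "recipient": rec, "donor": don})
                pre = {s: (s in consortia[rec]) for s in universe}
                post = {}
                for s in universe:
                    if s in consortia[rec]:
                        post[s] = bool(rng.random() < persist_p)
                    elif s in consortia[don]:
                        post[s] = bool(rng.random() < engraft_p)
                    else:
                        post[s] = False
                pres_rows.append(pd.Series(pre, name=(mouse, "pre")))
                pres_rows.append(pd.Series(post, name=(mouse, "post")))
    presence = pd.DataFrame(pres_rows)
    presence.index = pd.MultiIndex.from_tuples(presence.index, names=["mouse_id", "timepoint"])
    return presence, pd.DataFrame(meta_rows).set_index("mouse_id"), consortia
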