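"""Synthetic sequencing inputs with controlled, recoverable latent structure.

Three generators mirror the three front-ends:

* :func:`simulate_reads` — FASTQ lanes of per-sample reads drawn from
  species-specific order-1 Markov chains, with optional repeat-family
  enrichment, adapter read-through spike-ins (the adapter replaces part of
  the read), and near-uniform negative-control samples.  Species differ in
  their transition tables, which gives them distinct 6-mer zipfian curves.
* :func:`simulate_hit_table` — query loci placed along a virtual genome as
  a mixture of dense clusters and sparse background, viewed through a
  panel of references that may each relocate a segment (a rearrangement),
  with percent identities drawn from a Beta distribution.
* :func:`simulate_taxa_table` — multinomial taxonomy hit counts per batch,
  where batches of the same nominal species share a Dirichlet-perturbed
  base profile over an opaque taxon pool.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aligninfo import HitTable
from .errors import PrismError
from .taxa import TaxaTable

__all__ = [
    "DEFAULT_ADAPTER",
    "SpeciesProfile",
    "SampleSpec",
    "LaneConfig",
    "Relocation",
    "random_species",
    "simulate_reads",
    "write_fastq",
    "simulate_hit_table",
    "simulate_taxa_table",
    "two_species_lane",
    "spiked_sample",
    "rearranged_panel",
]

_BASES = np.array(list("ACGT"))

#: default spiked adapter: 38 bases = 33 overlapping 6-mers, all distinct,
#: so a complete read-through contaminant is recoverable by greedy assembly
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGCTA"


@dataclass
class SpeciesProfile:
    """Order-1 Markov model of a species' genome composition.

    ``transition`` is a 4x4 row-stochastic matrix over (A, C, G, T);
    ``repeat_families`` lists (unit sequence, genome fraction) pairs — a
    read is drawn from tiled copies of a repeat unit with probability equal
    to its fraction.  ``uniformity`` is recorded metadata (the Dirichlet
    concentration used by :func:`random_species`).
    """

    name: str
    transition: np.ndarray
    repeat_families: list[tuple[str, float]] = field(default_factory=list)
    uniformity: float | None = None

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (4, 4):
            raise PrismError("invalid-profile", "transition must be 4x4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise PrismError("invalid-profile", "transition rows must sum to 1")
        frac = sum(f for _, f in self.repeat_families)
        if any(not (0 <= f < 1) for _, f in self.repeat_families) or frac >= 1:
            raise PrismError("invalid-profile", "repeat fractions must sum to < 1")


def random_species(
    name: str, seed: int, uniformity: float = 60.0,
    repeat_families: Sequence[tuple[str, float]] = (),
) -> SpeciesProfile:
    """Draw a species transition table from a symmetric Dirichlet.

    Each row of the transition matrix is Dirichlet(uniformity / 4) — large
    ``uniformity`` gives near-uniform composition (flat zipfian curve),
    small values give skewed composition (steep curve, repeat-rich-like).
    Distinct seeds give species with distinct k-mer spectra.
    """
    rng = np.random.default_rng(seed)
    trans = rng.dirichlet(np.full(4, uniformity / 4.0), size=4)
    return SpeciesProfile(
        name=name, transition=trans,
        repeat_families=list(repeat_families), uniformity=uniformity,
    )


@dataclass
class SampleSpec:
    """One sample in a lane."""

    sample_id: str
    profile: SpeciesProfile | None  # None for negative controls
    n_reads: int = 300
    read_length: int = 101
    adapter: str | None = None
    adapter_rate: float = 0.0

    def __post_init__(self):
        if self.n_reads < 0:
            raise PrismError("invalid-config", "n_reads must be >= 0")
        if not (0.0 <= self.adapter_rate <= 1.0):
            raise PrismError("invalid-config", "adapter_rate must be in [0, 1]")


@dataclass
class LaneConfig:
    """A multiplexed sequencing lane: samples plus negative controls."""

    samples: list[SampleSpec]
    negative_controls: list[str] = field(default_factory=list)
    seed: int = 0


def _markov_batch(rng: np.random.Generator, trans: np.ndarray,
                  n: int, length: int) -> np.ndarray:
    """n Markov-chain reads of the given length, as a (n, length) code array."""
    cum = np.cumsum(trans, axis=1)
    # start states from the uniform distribution (burn-in is negligible at
    # read scale and keeps the generator simple)
    states = rng.integers(0, 4, size=n)
    out = np.empty((n, length), dtype=np.int8)
    out[:, 0] = states
    for pos in range(1, length):
        u = rng.random(n)
        states = (cum[states] < u[:, None]).sum(axis=1)
        out[:, pos] = states
    return out


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    return ["".join(row) for row in _BASES[codes]]


#: iid base composition of negative-control samples: near-uniform, so their
#: zipfian curves are nearly flat and visually separate from biological ones
_CONTROL_BASE_P = np.array([0.28, 0.22, 0.22, 0.28])


def _sample_reads(spec: SampleSpec, is_control: bool,
                  rng: np.random.Generator) -> list[str]:
    n, L = spec.n_reads, spec.read_length
    if n == 0:
        return []
    if is_control or spec.profile is None:
        codes = rng.choice(4, size=(n, L), p=_CONTROL_BASE_P)
    else:
        prof = spec.profile
        codes = _markov_batch(rng, prof.transition, n, L)
        for unit, frac in prof.repeat_families:
            take = rng.random(n) < frac
            idx = np.flatnonzero(take)
            if len(idx) == 0:
                continue
            ucodes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in unit],
                              dtype=np.int8)
            tiled = np.tile(ucodes, L // len(ucodes) + 2)
            offs = rng.integers(0, len(ucodes), size=len(idx))
            for i, off in zip(idx, offs):
                codes[i] = tiled[off:off + L]
    reads = _codes_to_strings(codes)
    if spec.adapter and spec.adapter_rate > 0:
        ad = spec.adapter
        hit = rng.random(n) < spec.adapter_rate
        lo = L // 2
        hi = max(lo + 1, L - len(ad) + 1)
        starts = rng.integers(lo, hi, size=n)
        for i in np.flatnonzero(hit):
            s = int(starts[i])
            r = reads[i]
            reads[i] = (r[:s] + ad + r[s + len(ad):])[:L]
    return reads


def simulate_reads(cfg: LaneConfig, out_dir: str | Path | None = None
                   ) -> dict[str, list[str]]:
    """Simulate a lane; returns sample_id -> reads, optionally writing FASTQ.

    Fully seeded: each sample's stream is seeded by (lane seed, sample
    index), so identical configurations produce byte-identical FASTQ.
    """
    controls = set(cfg.negative_controls)
    out: dict[str, list[str]] = {}
    for idx, spec in enumerate(cfg.samples):
        rng = np.random.default_rng([cfg.seed, idx])
        out[spec.sample_id] = _sample_reads(spec, spec.sample_id in controls, rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, reads in out.items():
            write_fastq(reads, out_dir / f"{sid}.fastq", prefix=sid)
    return out


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read"
                ) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{r}\n+\n{'I' * len(r)}\n")
    return path


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Relocation:
    """Relocate the base-layout segment [start, end) to begin at ``dest``."""

    start: int
    end: int
    dest: int


def simulate_hit_table(
    n_queries: int,
    references: Sequence[tuple[str, Relocation | None]],
    seed: int = 0,
    genome_length: int = 1_000_000,
    clusters: Sequence[tuple[int, int, int]] | None = None,
    sparse_range: tuple[int, int] | None = None,
    dense_fraction: float = 0.7,
    n_clusters: int = 5,
    cluster_sd: int = 300,
) -> HitTable:
    """Best-hit table of clustered query loci against a reference panel.

    Queries occupy a base layout on a single virtual contig: either an
    explicit list of ``clusters`` (centre, n, sd) plus uniform sparse
    queries over ``sparse_range``, or a random mixture where a
    ``dense_fraction`` of queries fall into ``n_clusters`` Gaussian
    clusters and the rest are uniform.  Each reference sees the same layout
    through an optional :class:`Relocation` coordinate transform.  Percent
    identities are drawn once per query from 80 + 20 * Beta(8, 2).
    """
    if len(references) == 0:
        raise PrismError("empty-panel", "need at least one reference")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    if clusters is not None:
        for centre, n, sd in clusters:
            positions.append(rng.normal(centre, sd, size=n))
        placed = sum(n for _, n, _ in clusters)
        n_sparse = n_queries - placed
        if n_sparse < 0:
            raise PrismError("invalid-config", "clusters exceed n_queries")
        lo, hi = sparse_range if sparse_range else (0, genome_length)
        positions.append(rng.uniform(lo, hi, size=n_sparse))
    else:
        n_dense = int(round(dense_fraction * n_queries))
        centres = rng.uniform(0, genome_length, size=n_clusters)
        assign = rng.integers(0, n_clusters, size=n_dense)
        positions.append(centres[assign] + rng.normal(0, cluster_sd, size=n_dense))
        positions.append(rng.uniform(0, genome_length, size=n_queries - n_dense))
    base = np.clip(np.concatenate(positions), 0, genome_length - 1).astype(int)
    pctid = 80.0 + 20.0 * rng.beta(8.0, 2.0, size=n_queries)
    qids = [f"q{i:06d}" for i in range(n_queries)]
    rows = []
    for ref_id, reloc in references:
        pos = base.copy()
        if reloc is not None:
            inside = (base >= reloc.start) & (base < reloc.end)
            pos = np.where(inside, base - reloc.start + reloc.dest, base)
        for q, p, pid in zip(qids, pos, pctid):
            rows.append((q, ref_id, "chr1", int(p), float(pid)))
    df = pd.DataFrame(
        rows, columns=["query_id", "reference_id", "contig", "pos", "pct_identity"]
    )
    return HitTable(df, reduced=True)


# ---------------------------------------------------------------------------
# canned study conditions (shared by tests, examples and the acceptance run)
# ---------------------------------------------------------------------------


def two_species_lane(
    seed: int, n_a: int = 150, n_b: int = 42,
    n_reads: int = 300, uniformity: float = 60.0,
) -> tuple[LaneConfig, list[int]]:
    """A GBS-like lane mixing two species (e.g. cattle plus stray deer).

    Returns the lane configuration and the 0/1 species label per sample.
    The two species' transition tables are fixed (independent of ``seed``,
    which only drives the reads), so the latent structure is the same
    across replicate lanes.
    """
    sp_a = random_species("speciesA", seed=11, uniformity=uniformity)
    sp_b = random_species("speciesB", seed=22, uniformity=uniformity)
    samples = [
        SampleSpec(f"A{i:03d}", sp_a, n_reads=n_reads) for i in range(n_a)
    ] + [
        SampleSpec(f"B{i:03d}", sp_b, n_reads=n_reads) for i in range(n_b)
    ]
    labels = [0] * n_a + [1] * n_b
    return LaneConfig(samples, seed=seed), labels


def spiked_sample(
    seed: int, adapter_rate: float, n_reads: int = 2000,
    adapter: str = DEFAULT_ADAPTER, uniformity: float = 800.0,
) -> SampleSpec:
    """One sample with adapter read-through at the given rate.

    The background species is near-uniform (high ``uniformity``) so the
    planted adapter's k-mers occupy the top zipfian ranks, as adapter
    contamination does against the diverse word background of real data.
    """
    sp = random_species("background", seed=1000 + seed, uniformity=uniformity)
    return SampleSpec(
        "spiked" if adapter_rate > 0 else "clean",
        sp, n_reads=n_reads, read_length=101,
        adapter=adapter, adapter_rate=adapter_rate,
    )


def rearranged_panel(seed: int = 0) -> tuple[HitTable, tuple[int, int]]:
    """Two-reference hit table where reference B relocates one segment.

    The base layout has a dense cluster (200 queries), an isolated segment
    holding 20 queries, and sparse background; reference B moves the
    segment into the middle of the dense cluster.  Returns the hit table
    (references ``refA``/``refB``) and the segment interval in base-layout
    coordinates: queries inside it change windowed depth under exactly one
    reference.
    """
    seg = (100_000, 102_000)
    refs = [("refA", None), ("refB", Relocation(seg[0], seg[1], 499_500))]
    ht = simulate_hit_table(
        250, refs, seed=seed,
        clusters=[(500_500, 200, 300), (101_000, 20, 150)],
        sparse_range=(200_000, 400_000),
    )
    return ht, seg


# ---------------------------------------------------------------------------
# taxa tables
# ---------------------------------------------------------------------------


def simulate_taxa_table(
    batches: Sequence[Sequence[tuple[str, float]]],
    n_hits: int = 2000,
    seed: int = 0,
    taxon_pool: int = 40,
    concentration: float = 500.0,
    batch_ids: Sequence[str] | None = None,
    species_seed: int = 0,
) -> TaxaTable:
    """Multinomial taxonomy hit counts for a series of batches.

    Each batch is a species mix, a list of (species name, weight) with
    weights normalising to 1.  Every species has a Dirichlet(1.0) base
    profile over the opaque taxon pool (derived from the species name and
    ``species_seed`` only — not from ``seed`` — so batches naming the same
    species share it even across separately generated tables); a batch's profile is the
    weighted mix of Dirichlet(concentration * base) perturbations of its
    species' bases, and its counts are one multinomial draw of ``n_hits``.
    The concentration keeps replicate batches of one species much closer
    to each other than to batches of any other species.
    """
    rng = np.random.default_rng(seed)
    species = sorted({name for mix in batches for name, _ in mix})
    bases = {}
    for s in species:
        # stable per-species stream: Python's hash() is salted per process
        tag = zlib.crc32(s.encode()) % (2**31)
        srng = np.random.default_rng([species_seed, tag])
        bases[s] = srng.dirichlet(np.full(taxon_pool, 1.0))
    taxa = [f"taxon_{i:03d}" for i in range(taxon_pool)]
    ids = (
        list(batch_ids)
        if batch_ids is not None
        else [f"batch_{i:03d}" for i in range(len(batches))]
    )
    counts = np.zeros((len(batches), taxon_pool), dtype=np.int64)
    for i, mix in enumerate(batches):
        w = np.array([wt for _, wt in mix], dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise PrismError("invalid-config", "mix weights must sum to 1")
        profile = np.zeros(taxon_pool)
        for (name, wt) in mix:
            base = bases[name]
            pert = rng.dirichlet(concentration * base + 0.01)
            profile += wt * pert
        profile /= profile.sum()
        counts[i] = rng.multinomial(n_hits, profile)
    return TaxaTable(batch_ids=ids, taxa=taxa, counts=counts)
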