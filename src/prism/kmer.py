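"""k-mer front-end: empirical k-mer probability models and zipfian co-spectra.

A sequencing file is summarised by the frequencies of its DNA k-mers
(k = 6 by default), optionally after Bernoulli subsampling of whole reads.
The resulting empirical probability model yields, per file, a *zipfian
co-spectrum*: the ordered (rank, self-information) pairs of all observed
k-mers, the matrix-valued <R, I> representation of the file.  Plotted as
self-information against log rank these curves are linear for power-law
word frequencies; their slope tracks repeat content and sharp turning
points flag technical artefacts such as adapter read-through, whose
co-abundant k-mers can then be greedily assembled back into the
contaminant sequence.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ProbabilityModel, unobserved_self_information
from .errors import PrismError

__all__ = [
    "KmerProfile",
    "ZipfianCoSpectrum",
    "count_kmers",
    "kmer_probability_model",
    "zipfian_cospectrum",
    "zipfian_from_profile",
    "detect_turning_points",
    "assemble_enriched_kmers",
]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class KmerProfile:
    """k-mer counts of one (possibly subsampled) sequence file."""

    k: int
    counts: dict[str, int]
    total: int
    sampled_fraction: float = 1.0
    seed: int = 0
    canonicalisation: str = "as-is"  # or "lexmin-of-strand"
    source: str = ""

    def __post_init__(self):
        if self.total != sum(self.counts.values()):
            raise PrismError("count-mismatch", "total != sum of counts")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["kmer", "count"]
        )
        df.to_csv(path, sep="\t", index=False)
        meta = {
            "k": self.k,
            "total": self.total,
            "sampled_fraction": self.sampled_fraction,
            "seed": self.seed,
            "canonicalisation": self.canonicalisation,
            "source": self.source,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerProfile":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        counts = dict(zip(df["kmer"], df["count"]))
        return cls(
            k=meta["k"],
            counts=counts,
            total=meta["total"],
            sampled_fraction=meta["sampled_fraction"],
            seed=meta["seed"],
            canonicalisation=meta["canonicalisation"],
            source=meta.get("source", ""),
        )


def _decode(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode()


def _iter_records(source, fmt: str | None) -> Iterator[str]:
    """Yield sequence strings from a path, handle, or iterable of sequences."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name.lower()
        opener = gzip.open if name.endswith(".gz") else open
        stem = name[:-3] if name.endswith(".gz") else name
        if fmt is None:
            if stem.endswith((".fq", ".fastq")):
                fmt = "fastq"
            else:
                fmt = "fasta"
        with opener(path, "rt") as fh:
            idx = -1
            try:
                for idx, rec in enumerate(SeqIO.parse(fh, fmt)):
                    yield str(rec.seq)
            except ValueError as exc:
                raise PrismError("parse-error", f"record {idx + 1}: {exc}") from exc
        return
    for item in source:
        yield str(getattr(item, "seq", item))


def _count_batch(
    seqs: Sequence[str], k: int, canonical: bool
) -> np.ndarray:
    """Count k-mer codes over a batch of sequences (joined with N spacers)."""
    joined = ("N" * k).join(seqs)
    codes = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        return np.zeros(4**k, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kcodes = win @ powers
    if canonical:
        rc = (3 - win)[:, ::-1] @ powers
        kcodes = np.minimum(kcodes, rc)
    return np.bincount(kcodes[valid], minlength=4**k)


def count_kmers(
    source,
    k: int = 6,
    sample_rate: float = 1.0,
    seed: int = 0,
    canonicalisation: str = "as-is",
    fmt: str | None = None,
) -> KmerProfile:
    """Count all overlapping k-mers of a (subsampled) read set.

    Reads are retained independently with probability ``sample_rate``
    (seeded Bernoulli, whole-record sampling); every overlapping window of
    a retained read is counted, except windows containing a non-ACGT
    symbol.  ``canonicalisation="lexmin-of-strand"`` folds each k-mer with
    its reverse complement; the default counts k-mers as written, which is
    what adapter and other strand-specific contaminant diagnostics need.

    ``source`` may be a FASTA/FASTQ path (plain or gzip), an open iterable
    of Bio.SeqRecord, or an iterable of plain sequence strings.
    """
    if k < 1:
        raise PrismError("invalid-k", str(k))
    if not (0.0 < sample_rate <= 1.0):
        raise PrismError("invalid-sample-rate", str(sample_rate))
    if canonicalisation not in ("as-is", "lexmin-of-strand"):
        raise PrismError("invalid-canonicalisation", canonicalisation)
    rng = np.random.default_rng(seed)
    counts = np.zeros(4**k, dtype=np.int64)
    retained = 0
    batch: list[str] = []
    batch_len = 0
    for seq in _iter_records(source, fmt):
        if sample_rate < 1.0 and rng.random() >= sample_rate:
            continue
        retained += 1
        batch.append(seq)
        batch_len += len(seq)
        if batch_len >= 1_000_000:
            counts += _count_batch(batch, k, canonicalisation != "as-is")
            batch, batch_len = [], 0
    if batch:
        counts += _count_batch(batch, k, canonicalisation != "as-is")
    if retained == 0:
        raise PrismError("empty-sample", "no reads retained by subsampling")
    nz = np.flatnonzero(counts)
    cdict = {_decode(int(c), k): int(counts[c]) for c in nz}
    return KmerProfile(
        k=k,
        counts=cdict,
        total=int(counts.sum()),
        sampled_fraction=sample_rate,
        seed=seed,
        canonicalisation=canonicalisation,
        source=str(source) if isinstance(source, (str, Path)) else "",
    )


def kmer_probability_model(profile: KmerProfile, model_id: str | None = None
                           ) -> ProbabilityModel:
    """Empirical probability model p(w) = count(w) / total over observed k-mers."""
    if profile.total <= 0:
        raise PrismError("empty-sample", "profile has no counted k-mers")
    return ProbabilityModel.from_counts(
        model_id if model_id is not None else (profile.source or "kmer"),
        profile.counts,
    )


@dataclass
class ZipfianCoSpectrum:
    """Ordered (rank, self-information) pairs of one probability model.

    Ranks run 1..D over the D observed bins, sorted by descending
    probability (ties broken lexicographically by bin key), with
    h = -ln p in nats.  The bin key at each rank is retained so that two
    co-spectra can be aligned bin-by-bin when computing distances.
    """

    model_id: str
    k: int
    total: int
    ranks: np.ndarray  # int, 1..D
    h: np.ndarray  # nats, non-decreasing
    bins: list[str]
    counts: np.ndarray | None = None

    def __post_init__(self):
        d = len(self.ranks)
        if not (len(self.h) == len(self.bins) == d):
            raise PrismError("length-mismatch", "zipfian arrays differ in length")
        if d and (np.diff(self.h) < -1e-12).any():
            raise PrismError("unsorted-cospectrum", "h must be non-decreasing in rank")

    @property
    def pairs(self) -> list[tuple[int, float]]:
        return list(zip(self.ranks.tolist(), self.h.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "rank": self.ranks,
                "kmer": self.bins,
                "count": self.counts if self.counts is not None else np.nan,
                "p": np.exp(-self.h),
                "h": self.h,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def zipfian_cospectrum(model: ProbabilityModel, k: int | None = None
                       ) -> ZipfianCoSpectrum:
    """The <R, I> matrix co-spectrum of one probability model.

    Observed bins are sorted by descending probability (lexicographic
    tie-break), ranked 1..D and paired with their self-information
    h = -ln p.  Storage keeps raw ranks; plots use ln(rank) on the x axis.
    """
    keep = [
        (b, p) for b, p in zip(model.bins, model.probs) if p > 0
    ]
    if not keep:
        raise PrismError("empty-sample", f"model {model.id!r} has no observed bins")
    keep.sort(key=lambda bp: (-bp[1], bp[0]))
    bins = [b for b, _ in keep]
    probs = np.array([p for _, p in keep])
    h = -np.log(probs)
    if k is None:
        k = len(str(bins[0]))
    counts = np.rint(probs * model.total_count).astype(np.int64)
    return ZipfianCoSpectrum(
        model_id=model.id,
        k=int(k),
        total=model.total_count,
        ranks=np.arange(1, len(bins) + 1, dtype=np.int64),
        h=h,
        bins=[str(b) for b in bins],
        counts=counts,
    )


def zipfian_from_profile(profile: KmerProfile, model_id: str | None = None
                         ) -> ZipfianCoSpectrum:
    """Convenience: profile -> probability model -> zipfian co-spectrum."""
    return zipfian_cospectrum(kmer_probability_model(profile, model_id), k=profile.k)


def detect_turning_points(
    z: ZipfianCoSpectrum,
    window: int = 9,
    threshold_factor: float = 3.0,
    min_curvature: float = 1.5,
    tail_exclude: float = 0.10,
    n_grid: int = 200,
) -> list[tuple[int, float]]:
    """Locate turning points of the zipfian function h(ln rank).

    The curve is resampled onto a uniform grid in ln(rank), smoothed with a
    centred moving window, and the discrete second derivative taken.  Local
    extrema whose |second derivative| exceeds both ``threshold_factor`` times
    the median absolute second derivative and the absolute floor
    ``min_curvature`` (nats per unit ln-rank squared; guards the exactly
    linear case, where the median is pure float noise, and the gentle global
    curvature every finite sample shows) are reported as (rank, curvature
    score), sorted by decreasing |score|.  The rightmost ``tail_exclude``
    fraction of the ln-rank range is skipped: the sharp upturn among the
    rarest words is present in every finite sample and carries no artefact
    signal.  A curve that is linear in ln-rank — the power-law / zipfian
    null — yields an empty list.
    """
    d = len(z.ranks)
    if d < 3 * window:
        raise PrismError(
            "insufficient-points", f"need >= {3 * window} ranks, got {d}"
        )
    x = np.log(z.ranks.astype(float))
    y = z.h
    grid = np.linspace(x[0], x[-1], n_grid)
    yg = np.interp(grid, x, y)
    ys = pd.Series(yg).rolling(window, center=True, min_periods=1).mean().to_numpy()
    dx = grid[1] - grid[0]
    d2 = np.gradient(np.gradient(ys, dx), dx)
    mad = float(np.median(np.abs(d2[window:-window])))
    thr = max(threshold_factor * mad, min_curvature)
    out: list[tuple[int, float]] = []
    lo = window  # grid edges are boundary artefacts of the smoother
    x_cut = grid[-1] - tail_exclude * (grid[-1] - grid[0])
    hi = int(np.searchsorted(grid, x_cut, side="right"))
    hi = min(hi, n_grid - window)
    absd2 = np.abs(d2)
    for i in range(max(lo, 1), min(hi, n_grid - 1)):
        if absd2[i] > thr and absd2[i] >= absd2[i - 1] and absd2[i] >= absd2[i + 1]:
            rank = int(round(math.exp(grid[i])))
            out.append((rank, float(d2[i])))
    out.sort(key=lambda rs: -abs(rs[1]))
    # merge duplicate ranks from plateaus of |d2|
    seen: set[int] = set()
    dedup = []
    for r, s in out:
        if r not in seen:
            seen.add(r)
            dedup.append((r, s))
    return dedup


def _select_kmers(
    z: ZipfianCoSpectrum,
    rank_range: tuple[int, int] | None,
    max_h: float | None,
) -> list[tuple[str, int]]:
    sel = np.ones(len(z.ranks), dtype=bool)
    if rank_range is not None:
        lo, hi = rank_range
        sel &= (z.ranks >= lo) & (z.ranks <= hi)
    if max_h is not None:
        sel &= z.h <= max_h
    counts = (
        z.counts
        if z.counts is not None
        else np.rint(np.exp(-z.h) * z.total).astype(np.int64)
    )
    return [(z.bins[i], int(counts[i])) for i in np.flatnonzero(sel)]


def assemble_enriched_kmers(
    profile_or_z: "KmerProfile | ZipfianCoSpectrum",
    rank_range: tuple[int, int] | None = None,
    max_h: float | None = None,
    min_overlap: int | None = None,
) -> list[str]:
    """Greedy overlap assembly of a selected (enriched) k-mer set.

    Selection is by zipfian rank range and/or self-information threshold
    (``h <= max_h``); with neither given, every observed k-mer is used.
    Assembly repeatedly merges the pair of fragments with the maximal exact
    suffix-prefix overlap (>= ``min_overlap``, default k-1), breaking ties
    by higher combined count then lexicographically, until no admissible
    overlap remains.  Fragments fully contained in another are absorbed.
    Returns contigs sorted by decreasing length (ties lexicographic).
    """
    z = (
        zipfian_from_profile(profile_or_z)
        if isinstance(profile_or_z, KmerProfile)
        else profile_or_z
    )
    if min_overlap is None:
        min_overlap = z.k - 1
    frags = _select_kmers(z, rank_range, max_h)
    if not frags:
        raise PrismError("empty-selection", "no k-mers selected for assembly")
    contigs: list[list] = [[s, c] for s, c in frags]

    def overlap(a: str, b: str) -> int:
        m = min(len(a), len(b))
        for ell in range(m, min_overlap - 1, -1):
            if a.endswith(b[:ell]):
                return ell
        return 0

    while len(contigs) > 1:
        best = None  # (ov, combined, a_seq, b_seq, ia, ib)
        for ia in range(len(contigs)):
            for ib in range(len(contigs)):
                if ia == ib:
                    continue
                a, ca = contigs[ia]
                b, cb = contigs[ib]
                if b in a:  # containment absorbs
                    ov = len(b)
                else:
                    ov = overlap(a, b)
                if ov < min_overlap:
                    continue
                cand = (ov, ca + cb, a, b, ia, ib)
                if best is None or (
                    cand[0],
                    cand[1],
                    # lexicographic pair preference: smaller sorts first
                    tuple(-ord(ch) for ch in cand[2]),
                    tuple(-ord(ch) for ch in cand[3]),
                ) > (
                    best[0],
                    best[1],
                    tuple(-ord(ch) for ch in best[2]),
                    tuple(-ord(ch) for ch in best[3]),
                ):
                    best = cand
        if best is None:
            break
        ov, comb, a, b, ia, ib = best
        merged = a if b in a else a + b[ov:]
        keep = [contigs[i] for i in range(len(contigs)) if i not in (ia, ib)]
        keep.append([merged, comb])
        contigs = keep
    return sorted((s for s, _ in contigs), key=lambda s: (-len(s), s))
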