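"""Alignment front-end: windowed-depth probability models over a reference panel.

Hit tables (BLAST outfmt-6-like) of a query collection against a panel of
reference assemblies are reduced to best hits and converted, per reference,
into an empirical probability model: the probability of a query is its
alignment depth in a window centred on its alignment position, divided by
the total number of queries aligned to that reference.  A query landing
in a dense region is unsurprising (low self-information); a query aligning
where nothing else does is surprising (high self-information).  Combining
the per-reference models with the self-information operator yields a
spectrum per query across the panel — a non-semantic annotation of the
query — and, dually, an information co-spectrum per reference.  A separate
representation labels references by the best-hit percent identity of each
probe against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ProbabilityModel,
    SpectrumTensor,
    unobserved_self_information,
)
from .errors import PrismError

__all__ = [
    "HitTable",
    "read_blast_outfmt6",
    "read_hits_tsv",
    "read_hits_sam",
    "best_hits",
    "windowed_depth_model",
    "panel_information_tensor",
    "pctid_cospectra",
]

_COLUMNS = ["query_id", "reference_id", "contig", "pos", "pct_identity"]


@dataclass
class HitTable:
    """Alignment hits: (query, reference assembly, contig, 0-based pos, %id)."""

    df: pd.DataFrame
    reduced: bool = False  # True once at most one row per (query, reference)

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise PrismError("missing-columns", ", ".join(missing))
        if len(self.df) and (self.df["pos"] < 0).any():
            raise PrismError("invalid-position", "positions must be >= 0")
        pid = self.df["pct_identity"]
        if len(self.df) and ((pid < 0) | (pid > 100)).any():
            raise PrismError("invalid-identity", "pct_identity must be in [0, 100]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def references(self) -> list[str]:
        return sorted(self.df["reference_id"].unique())

    def aligned_totals(self) -> dict[str, int]:
        """Distinct queries aligned per reference."""
        return (
            self.df.groupby("reference_id")["query_id"].nunique().to_dict()
        )

    def to_tsv(self, path: str | Path) -> None:
        self.df[_COLUMNS].to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> HitTable:
    """Read the minimal internal TSV (query, ref, contig, pos, pctid)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"query_id": str, "reference_id": str, "contig": str},
    )
    return HitTable(df[_COLUMNS].copy())


def read_blast_outfmt6(path: str | Path, reference_id: str) -> HitTable:
    """Read BLAST tabular output (outfmt 6) as hits against one reference.

    ``sseqid`` becomes the contig within ``reference_id``; the subject start
    (min of sstart/send, converted to 0-based) becomes the position.
    """
    names = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=names, comment="#",
                     dtype={"qseqid": str, "sseqid": str})
    out = pd.DataFrame(
        {
            "query_id": df["qseqid"],
            "reference_id": reference_id,
            "contig": df["sseqid"],
            "pos": np.minimum(df["sstart"], df["send"]).astype(int) - 1,
            "pct_identity": df["pident"].astype(float),
        }
    )
    return HitTable(out)


def read_hits_sam(path: str | Path, reference_id: str) -> HitTable:
    """Map each primary SAM alignment to (contig, pos, identity from NM)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            alen = rec.query_alignment_length or 0
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            pid = 100.0 * (alen - nm) / alen if alen else 0.0
            rows.append(
                (rec.query_name, reference_id, rec.reference_name,
                 rec.reference_start, pid)
            )
    return HitTable(pd.DataFrame(rows, columns=_COLUMNS))


def concat_hits(tables: Sequence[HitTable]) -> HitTable:
    return HitTable(pd.concat([t.df for t in tables], ignore_index=True))


def best_hits(raw: HitTable) -> HitTable:
    """Keep, per (query, reference), the single best row.

    Best = max percent identity; ties resolved by smallest position, then
    lexicographically smallest contig name (deterministic).
    """
    df = raw.df.sort_values(
        ["query_id", "reference_id", "pct_identity", "pos", "contig"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(["query_id", "reference_id"], keep="first")
    return HitTable(df.reset_index(drop=True), reduced=True)


def windowed_depth_model(
    hits: HitTable, reference_id: str, window: int = 2000
) -> ProbabilityModel:
    """Per-query window-depth probability model for one reference.

    For each query aligned to the reference, depth(x) counts the aligned
    queries whose best-hit position lies within the half-open window
    [c - window/2, c + window/2) centred on x's position c on the same
    contig (windows never span contigs); p(x) = depth(x) / total aligned.
    The result is an unnormalised probability model over query ids: each
    query's probability is computed in its own window, so the values need
    not sum to one.
    """
    if window < 1:
        raise PrismError("invalid-window", str(window))
    tbl = hits if hits.reduced else best_hits(hits)
    sub = tbl.df[tbl.df["reference_id"] == reference_id]
    if len(sub) == 0:
        raise PrismError("unknown-reference", reference_id)
    total = sub["query_id"].nunique()
    half = window / 2.0
    qids: list[str] = []
    depths: list[int] = []
    for _, grp in sub.groupby("contig", sort=True):
        pos = grp["pos"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="mergesort")
        spos = pos[order]
        lo = np.searchsorted(spos, spos - half, side="left")
        hi = np.searchsorted(spos, spos + half, side="left")
        d = hi - lo
        ids = grp["query_id"].to_numpy()[order]
        qids.extend(ids.tolist())
        depths.extend(d.tolist())
    probs = np.asarray(depths, dtype=float) / total
    return ProbabilityModel(
        id=reference_id, bins=qids, probs=probs, total_count=total,
        normalised=False,
    )


def panel_information_tensor(
    hits: HitTable, references: Sequence[str], window: int = 2000
) -> SpectrumTensor:
    """Self-information spectra of every query across a reference panel.

    Returns an N x M x 1 tensor (operator panel {info}): rows are query
    spectra, columns are reference information co-spectra.  A (query,
    reference) pair with no alignment carries the unobserved pseudo-count
    self-information and is flagged.
    """
    if len(references) == 0:
        raise PrismError("empty-panel", "need at least one reference")
    tbl = hits if hits.reduced else best_hits(hits)
    models = {r: windowed_depth_model(tbl, r, window) for r in references}
    elements = sorted(tbl.df["query_id"].unique())
    ei = {e: i for i, e in enumerate(elements)}
    values = np.empty((len(elements), len(references), 1))
    flags: set = set()
    for j, r in enumerate(references):
        model = models[r]
        h_un = unobserved_self_information(model.total_count)
        col = np.full(len(elements), h_un)
        hs = -np.log(model.probs)
        for q, h in zip(model.bins, hs):
            col[ei[q]] = h
        aligned = set(model.bins)
        for e in elements:
            if e not in aligned:
                flags.add((e, r))
        values[:, j, 0] = col
    return SpectrumTensor(
        element_ids=elements,
        model_ids=list(references),
        operator_ids=["info"],
        values=values,
        flags=flags,
    )


def pctid_cospectra(
    hits: HitTable,
    references: Sequence[str],
    probes: Sequence[str] | None = None,
) -> SpectrumTensor:
    """Best-hit percent-identity co-spectra of a reference panel.

    b[j, i] is the best-hit percent identity of probe i against reference j;
    probes with no hit against a reference get 0 and a flag.  Returned as an
    N x M x 1 tensor with operator panel {pctid}; ``cospectrum_of`` yields
    each reference's co-spectrum.
    """
    tbl = hits if hits.reduced else best_hits(hits)
    if probes is None:
        probes = sorted(tbl.df["query_id"].unique())
    probes = list(probes)
    ei = {p: i for i, p in enumerate(probes)}
    values = np.zeros((len(probes), len(references), 1))
    flags = {(p, r) for p in probes for r in references}
    for row in tbl.df.itertuples(index=False):
        if row.query_id in ei and row.reference_id in references:
            j = list(references).index(row.reference_id)
            values[ei[row.query_id], j, 0] = row.pct_identity
            flags.discard((row.query_id, row.reference_id))
    return SpectrumTensor(
        element_ids=probes,
        model_ids=list(references),
        operator_ids=["pctid"],
        values=values,
        flags=flags,
    )
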