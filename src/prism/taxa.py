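"""Taxonomy-count front-end: batch co-spectra over the union of taxa names.

A sequencing facility's per-batch BLAST QC produces counts of top-hit
taxonomy names.  Each batch is labelled non-semantically by its
information co-spectrum over the union of all taxonomy names ever hit:
h(taxon) = -ln(count / batch total), with never-hit taxa flagged and given
the pseudo-count self-information.  Batches accumulate over time; adding
new batches re-unions the taxon universe and zero-backfills earlier
batches without changing their probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SpectrumTensor, unobserved_self_information
from .errors import PrismError

__all__ = ["TaxaTable", "taxa_information_cospectra", "cumulative_update"]


@dataclass
class TaxaTable:
    """batches x taxa hit-count matrix (taxa = union over all batches)."""

    batch_ids: list[str]
    taxa: list[str]
    counts: np.ndarray  # (B, T) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.batch_ids), len(self.taxa)):
            raise PrismError("length-mismatch", "counts shape != (batches, taxa)")
        if len(set(self.batch_ids)) != len(self.batch_ids):
            raise PrismError("duplicate-batch", "batch ids must be unique")
        if len(set(self.taxa)) != len(self.taxa):
            raise PrismError("duplicate-taxon", "taxa names must be unique")
        if (self.counts < 0).any():
            raise PrismError("negative-count", "counts must be >= 0")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TaxaTable":
        """Build from long format (batch, taxon, count); names are opaque
        strings, trimmed of surrounding whitespace only."""
        df = df.copy()
        df["batch"] = df["batch"].astype(str)
        df["taxon"] = df["taxon"].astype(str).str.strip()
        wide = (
            df.pivot_table(index="batch", columns="taxon", values="count",
                           aggfunc="sum", fill_value=0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        return cls(
            batch_ids=wide.index.tolist(),
            taxa=wide.columns.tolist(),
            counts=wide.to_numpy(dtype=np.int64),
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.batch_ids):
            for j, t in enumerate(self.taxa):
                if self.counts[i, j]:
                    rows.append((b, t, int(self.counts[i, j])))
        return pd.DataFrame(rows, columns=["batch", "taxon", "count"])

    def to_tsv(self, path: str | Path, wide: bool = False) -> None:
        path = Path(path)
        if wide:
            pd.DataFrame(self.counts, index=self.batch_ids,
                         columns=self.taxa).to_csv(path, sep="\t")
        else:
            self.to_long().to_csv(path, sep="\t", index=False)
        meta = {"batches": self.batch_ids, "n_taxa": len(self.taxa)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path, wide: bool = False) -> "TaxaTable":
        path = Path(path)
        if wide:
            df = pd.read_csv(path, sep="\t", index_col=0)
            return cls(
                batch_ids=[str(b) for b in df.index],
                taxa=[str(t) for t in df.columns],
                counts=df.to_numpy(dtype=np.int64),
            )
        return cls.from_long(pd.read_csv(path, sep="\t"))


def taxa_information_cospectra(table: TaxaTable) -> SpectrumTensor:
    """Information co-spectra of every batch over the shared taxon universe.

    Returns a T x B x 1 tensor (elements = taxa, models = batches, operator
    panel {info}); ``cospectrum_of(batch)`` is the batch's co-spectrum.
    Zero-count cells are flagged and carry the pseudo-count
    -ln(0.5 / (rowsum + 0.5)).
    """
    rowsums = table.counts.sum(axis=1)
    if (rowsums == 0).any():
        bad = [b for b, s in zip(table.batch_ids, rowsums) if s == 0]
        raise PrismError("empty-batch", ", ".join(bad))
    t_n, b_n = len(table.taxa), len(table.batch_ids)
    values = np.empty((t_n, b_n, 1))
    flags: set = set()
    for j, b in enumerate(table.batch_ids):
        c = table.counts[j].astype(float)
        h_un = unobserved_self_information(int(rowsums[j]))
        with np.errstate(divide="ignore"):
            h = -np.log(c / rowsums[j])
        h[c == 0] = h_un
        values[:, j, 0] = h
        for i in np.flatnonzero(c == 0):
            flags.add((table.taxa[i], b))
    return SpectrumTensor(
        element_ids=list(table.taxa),
        model_ids=list(table.batch_ids),
        operator_ids=["info"],
        values=values,
        flags=flags,
    )


def cumulative_update(store: TaxaTable | None, new_batches: TaxaTable
                      ) -> TaxaTable:
    """Union a new batch table into a cumulative store.

    The taxon universe is re-unioned (sorted); taxa previously absent from
    a batch are backfilled as zero counts, which downstream co-spectra flag
    as unobserved.  Existing batches' counts — hence probabilities — are
    unchanged.
    """
    if store is None or len(store.batch_ids) == 0:
        return new_batches
    dup = set(store.batch_ids) & set(new_batches.batch_ids)
    if dup:
        raise PrismError("duplicate-batch", ", ".join(sorted(dup)))
    taxa = sorted(set(store.taxa) | set(new_batches.taxa))
    ti = {t: j for j, t in enumerate(taxa)}
    batches = store.batch_ids + new_batches.batch_ids
    counts = np.zeros((len(batches), len(taxa)), dtype=np.int64)
    for i, _ in enumerate(store.batch_ids):
        for t, c in zip(store.taxa, store.counts[i]):
            counts[i, ti[t]] = c
    off = len(store.batch_ids)
    for i, _ in enumerate(new_batches.batch_ids):
        for t, c in zip(new_batches.taxa, new_batches.counts[i]):
            counts[off + i, ti[t]] = c
    return TaxaTable(batch_ids=batches, taxa=taxa, counts=counts)
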