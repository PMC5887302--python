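"""Entropy-reducing representation operators and the spectrum/co-spectrum duality.

A dataset of N elements is mapped through a panel of models and a panel of
scalar representation operators into an N x M x K tensor.  Row slices are
*spectra* (one data element across all models), column slices are
*co-spectra* (one model across all data elements); the duality between the
two is transposition of the same array, never a recomputation.

Scalar operators implemented here:

``mean``  constant representation by the collection mean
``sd``    constant representation by the collection standard deviation
``rank``  rank of the element under an ordering model (injective up to ties)
``bin``   centre of the element's bin under a binning model
``freq``  occupancy count of the element's bin under a binning model
``info``  self-information -ln p of the element under a probability model

The model-fitting operator (representation by a fitted value under a general
model of the data) is deliberately an extension point only; see
:func:`op_model_fit`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PrismError

LOG_BASE = math.e  # self-information is measured in nats throughout

__all__ = [
    "Element",
    "OrderingModel",
    "BinningModel",
    "ProbabilityModel",
    "SpectrumTensor",
    "Spectrum",
    "CoSpectrum",
    "op_mean",
    "op_sd",
    "op_rank",
    "op_bin",
    "op_freq",
    "op_model_fit",
    "self_information",
    "unobserved_self_information",
    "tensor_representation",
    "spectrum_of",
    "cospectrum_of",
    "OPERATOR_KINDS",
]


@dataclass(frozen=True)
class Element:
    """One data element: an opaque id and a payload (number, string, ...)."""

    id: str
    payload: object


def _payloads(dataset: Sequence) -> list:
    """Accept either a list of Elements or a list of bare payloads."""
    return [e.payload if isinstance(e, Element) else e for e in dataset]


def _ids(dataset: Sequence) -> list[str]:
    return [
        e.id if isinstance(e, Element) else f"e{i}" for i, e in enumerate(dataset)
    ]


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrderingModel:
    """A total order on payloads, given by a sort key and a direction.

    ``descending=True`` means rank 1 is assigned to the largest key.
    """

    id: str
    key: Callable[[object], object] = None  # type: ignore[assignment]
    descending: bool = False
    kind: str = field(default="ordering", init=False)

    def sort_key(self, payload):
        try:
            k = payload if self.key is None else self.key(payload)
        except Exception as exc:  # key function rejected the payload
            raise PrismError("unordered-element", f"{payload!r}: {exc}") from exc
        if k is None:
            raise PrismError("unordered-element", repr(payload))
        return k


@dataclass(frozen=True)
class BinningModel:
    """Maps every admissible payload to exactly one bin with a numeric centre.

    ``assign`` maps a payload to a bin key (or raises/returns None for an
    unbinnable payload); ``centre`` maps a bin key to its numeric centre.
    """

    id: str
    assign: Callable[[object], object]
    centre: Callable[[object], float]
    kind: str = field(default="binning", init=False)

    @staticmethod
    def uniform(id: str, width: float, origin: float = 0.0) -> "BinningModel":
        """Equal-width bins [origin + i*width, origin + (i+1)*width)."""

        def assign(x):
            return int(math.floor((float(x) - origin) / width))

        def centre(i):
            return origin + (i + 0.5) * width

        return BinningModel(id=id, assign=assign, centre=centre)

    def bin_of(self, payload):
        try:
            b = self.assign(payload)
        except Exception as exc:
            raise PrismError("unbinnable-element", f"{payload!r}: {exc}") from exc
        if b is None:
            raise PrismError("unbinnable-element", repr(payload))
        return b


class ProbabilityModel:
    """Empirical probability over a discrete bin universe.

    Parameters
    ----------
    bins:
        Distinct bin keys.
    probs:
        Per-bin probabilities (or unnormalised weights when
        ``normalised=False``; windowed alignment-depth models are of this
        kind because each element's probability is computed in its own
        window, so the values need not sum to one).
    total_count:
        Number of observations the probabilities were estimated from; used
        for the pseudo-count assigned to unobserved bins.
    """

    kind = "probability"

    def __init__(
        self,
        id: str,
        bins: Sequence,
        probs: Sequence[float],
        total_count: int,
        normalised: bool = True,
    ):
        self.id = id
        self.bins = list(bins)
        self.probs = np.asarray(probs, dtype=float)
        self.total_count = int(total_count)
        self.normalised = bool(normalised)
        self.log_base = LOG_BASE
        if len(self.bins) != len(set(self.bins)):
            raise PrismError("duplicate-bins", f"model {id!r}")
        if len(self.bins) != len(self.probs):
            raise PrismError("length-mismatch", f"model {id!r}")
        if np.any(self.probs < 0):
            raise PrismError("negative-probability", f"model {id!r}")
        if normalised and len(self.probs) and abs(self.probs.sum() - 1.0) > 1e-9:
            raise PrismError(
                "unnormalised-probabilities",
                f"model {id!r}: sum={self.probs.sum()!r}",
            )
        self._index = {b: i for i, b in enumerate(self.bins)}

    @classmethod
    def from_counts(cls, id: str, counts: Mapping, **kw) -> "ProbabilityModel":
        """Empirical model p(b) = count(b) / sum(counts)."""
        items = sorted(counts.items())
        total = sum(c for _, c in items)
        if total <= 0:
            raise PrismError("empty-sample", f"model {id!r}")
        bins = [b for b, _ in items]
        probs = np.array([c / total for _, c in items], dtype=float)
        return cls(id, bins, probs, total_count=total, **kw)

    def __contains__(self, bin_key) -> bool:
        return bin_key in self._index

    def probability(self, bin_key) -> float:
        i = self._index.get(bin_key)
        return 0.0 if i is None else float(self.probs[i])

    def unobserved(self, bin_key) -> bool:
        """True when the bin is absent or has zero probability."""
        i = self._index.get(bin_key)
        return i is None or self.probs[i] <= 0.0

    def __repr__(self) -> str:
        return (
            f"ProbabilityModel(id={self.id!r}, bins={len(self.bins)}, "
            f"total_count={self.total_count})"
        )


def unobserved_self_information(total_count: int) -> float:
    """Pseudo-count self-information for a bin the model never observed.

    Uses a half pseudo-count, p* = 0.5 / (total_count + 0.5), which is finite,
    exceeds every observed bin's self-information, and grows slowly with the
    size of the sample the model came from.
    """
    return -math.log(0.5 / (total_count + 0.5))


def self_information(model: ProbabilityModel, bin_key) -> float:
    """Self-information h = -ln p(bin_key) in nats.

    Bins the model never observed receive the pseudo-count value
    ``-ln(0.5 / (total_count + 0.5))``; use :meth:`ProbabilityModel.unobserved`
    to distinguish that case (tensor construction records it as a flag).
    """
    p = model.probability(bin_key)
    if p <= 0.0:
        return unobserved_self_information(model.total_count)
    return -math.log(p)


# ---------------------------------------------------------------------------
# scalar operators
# ---------------------------------------------------------------------------


def op_mean(dataset: Sequence) -> np.ndarray:
    """Represent every element by the collection mean (constant vector)."""
    xs = _payloads(dataset)
    if len(xs) == 0:
        raise PrismError("empty-dataset", "op_mean needs at least one element")
    m = float(np.mean(np.asarray(xs, dtype=float)))
    return np.full(len(xs), m)


def op_sd(dataset: Sequence, ddof: int = 1) -> np.ndarray:
    """Represent every element by the collection standard deviation."""
    xs = _payloads(dataset)
    if len(xs) < ddof + 1:
        raise PrismError(
            "insufficient-data", f"need at least {ddof + 1} elements, got {len(xs)}"
        )
    s = float(np.std(np.asarray(xs, dtype=float), ddof=ddof))
    return np.full(len(xs), s)


def op_rank(
    dataset: Sequence,
    ordering_model: OrderingModel,
    tie_rule: str = "ordinal-lexicographic",
) -> np.ndarray:
    """Rank of each element under the ordering model (1..N).

    ``ordinal-lexicographic`` breaks ties deterministically by element id;
    ``average`` assigns tied elements the mean of their ordinal ranks.
    """
    if tie_rule not in ("ordinal-lexicographic", "average"):
        raise PrismError("unknown-tie-rule", tie_rule)
    xs = _payloads(dataset)
    ids = _ids(dataset)
    keys = [ordering_model.sort_key(x) for x in xs]
    order = sorted(
        range(len(xs)),
        key=lambda i: (keys[i], ids[i]),
        reverse=False,
    )
    if ordering_model.descending:
        order = sorted(
            range(len(xs)),
            key=lambda i: (_Neg(keys[i]), ids[i]),
        )
    ranks = np.empty(len(xs), dtype=float)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    if tie_rule == "average":
        ser = pd.Series(keys)
        asc = not ordering_model.descending
        ranks = ser.rank(method="average", ascending=asc).to_numpy(dtype=float)
    return ranks


class _Neg:
    """Reverse-order wrapper so descending sorts keep id ties ascending."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __lt__(self, other):
        return other.v < self.v

    def __eq__(self, other):
        return self.v == other.v


def op_bin(dataset: Sequence, binning_model: BinningModel) -> np.ndarray:
    """Bin-centre representation of each element."""
    xs = _payloads(dataset)
    return np.array([binning_model.centre(binning_model.bin_of(x)) for x in xs])


def op_freq(dataset: Sequence, binning_model: BinningModel) -> np.ndarray:
    """Occupancy count of each element's parent bin."""
    xs = _payloads(dataset)
    bins = [binning_model.bin_of(x) for x in xs]
    counts: dict = {}
    for b in bins:
        counts[b] = counts.get(b, 0) + 1
    return np.array([counts[b] for b in bins], dtype=float)


def op_model_fit(*_args, **_kw):
    """Extension point for representation by a fitted model value.

    Not implemented: the framework defines the operator abstractly but no
    concrete model-fitting representation ships with the package.  See
    docs/methods.md ("Extension points").
    """
    raise PrismError(
        "not-implemented",
        "model-fit representation is an extension point; see docs/methods.md",
    )


# ---------------------------------------------------------------------------
# tensor combination
# ---------------------------------------------------------------------------

#: model kind each operator requires (None = model-independent)
OPERATOR_KINDS: dict[str, str | None] = {
    "mean": None,
    "sd": None,
    "rank": "ordering",
    "bin": "binning",
    "freq": "binning",
    "info": "probability",
}


@dataclass
class Spectrum:
    """Representation of one data element across the model panel (a view)."""

    owner_id: str
    model_ids: list[str]
    operator_ids: list[str]
    values: np.ndarray  # (M, K) view into the parent tensor


@dataclass
class CoSpectrum:
    """Representation of one model across all data elements (a view)."""

    owner_id: str
    element_ids: list[str]
    operator_ids: list[str]
    values: np.ndarray  # (N, K) view into the parent tensor


@dataclass
class SpectrumTensor:
    """elements x models x operators array with an unobserved-cell flag set.

    ``values[i, j, k]`` is operator ``operator_ids[k]`` applied to element
    ``element_ids[i]`` under model ``model_ids[j]``.  ``flags`` holds
    (element_id, model_id) pairs whose value came from the unobserved-bin
    pseudo-count rather than an observation.
    """

    element_ids: list[str]
    model_ids: list[str]
    operator_ids: list[str]
    values: np.ndarray
    flags: set = field(default_factory=set)

    def __post_init__(self):
        n, m, k = self.values.shape
        if (len(self.element_ids), len(self.model_ids), len(self.operator_ids)) != (
            n,
            m,
            k,
        ):
            raise PrismError("length-mismatch", "tensor axes do not match labels")
        self._ei = {e: i for i, e in enumerate(self.element_ids)}
        self._mi = {m_: j for j, m_ in enumerate(self.model_ids)}

    # -- duality ------------------------------------------------------------

    def spectrum_of(self, element_id: str) -> Spectrum:
        i = self._ei.get(element_id)
        if i is None:
            raise PrismError("unknown-id", element_id)
        return Spectrum(element_id, self.model_ids, self.operator_ids, self.values[i])

    def cospectrum_of(self, model_id: str) -> CoSpectrum:
        j = self._mi.get(model_id)
        if j is None:
            raise PrismError("unknown-id", model_id)
        return CoSpectrum(
            model_id, self.element_ids, self.operator_ids, self.values[:, j]
        )

    def subset_models(self, model_ids: Sequence[str]) -> "SpectrumTensor":
        """Sub-spectra: restrict the model panel (copies the sub-array)."""
        idx = []
        for m in model_ids:
            if m not in self._mi:
                raise PrismError("unknown-id", m)
            idx.append(self._mi[m])
        return SpectrumTensor(
            element_ids=list(self.element_ids),
            model_ids=list(model_ids),
            operator_ids=list(self.operator_ids),
            values=self.values[:, idx, :].copy(),
            flags={(e, m) for (e, m) in self.flags if m in set(model_ids)},
        )

    def flag_mask(self) -> np.ndarray:
        """Boolean (N, M) mask of unobserved cells."""
        mask = np.zeros((len(self.element_ids), len(self.model_ids)), dtype=bool)
        for e, m in self.flags:
            if e in self._ei and m in self._mi:
                mask[self._ei[e], self._mi[m]] = True
        return mask

    def operator_matrix(self, operator_id: str) -> np.ndarray:
        """The N x M matrix of one operator (rows spectra, cols co-spectra)."""
        try:
            k = self.operator_ids.index(operator_id)
        except ValueError:
            raise PrismError("unknown-id", operator_id) from None
        return self.values[:, :, k]

    # -- serialisation -------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write the TSV trio + JSON metadata serialisation."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"element_id": self.element_ids}).to_csv(
            path / "elements.tsv", sep="\t", index=False
        )
        pd.DataFrame({"model_id": self.model_ids}).to_csv(
            path / "models.tsv", sep="\t", index=False
        )
        rows = []
        for i, e in enumerate(self.element_ids):
            for j, m in enumerate(self.model_ids):
                fl = int((e, m) in self.flags)
                for k, op in enumerate(self.operator_ids):
                    rows.append((e, m, op, self.values[i, j, k], fl))
        pd.DataFrame(
            rows, columns=["element_id", "model_id", "operator_id", "value", "flag"]
        ).to_csv(path / "values.tsv", sep="\t", index=False)
        meta = {
            "log_base": "e",
            "operator_panel": self.operator_ids,
            "n_elements": len(self.element_ids),
            "n_models": len(self.model_ids),
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SpectrumTensor":
        path = Path(path)
        elements = pd.read_csv(path / "elements.tsv", sep="\t")["element_id"].astype(
            str
        ).tolist()
        models = pd.read_csv(path / "models.tsv", sep="\t")["model_id"].astype(
            str
        ).tolist()
        meta = json.loads((path / "metadata.json").read_text())
        ops = list(meta["operator_panel"])
        vals = pd.read_csv(path / "values.tsv", sep="\t", dtype={"element_id": str,
                                                                 "model_id": str})
        values = np.full((len(elements), len(models), len(ops)), np.nan)
        ei = {e: i for i, e in enumerate(elements)}
        mi = {m: j for j, m in enumerate(models)}
        oi = {o: k for k, o in enumerate(ops)}
        flags = set()
        for row in vals.itertuples(index=False):
            values[ei[row.element_id], mi[row.model_id], oi[row.operator_id]] = (
                row.value
            )
            if row.flag:
                flags.add((row.element_id, row.model_id))
        return cls(elements, models, ops, values, flags)


def _apply_operator(op: str, dataset: Sequence, model) -> tuple[np.ndarray, list[int]]:
    """Apply one scalar operator under one model; returns (vector, flagged idx)."""
    flagged: list[int] = []
    if op == "mean":
        return op_mean(dataset), flagged
    if op == "sd":
        return op_sd(dataset), flagged
    if op == "rank":
        return op_rank(dataset, model), flagged
    if op == "bin":
        return op_bin(dataset, model), flagged
    if op == "freq":
        return op_freq(dataset, model), flagged
    if op == "info":
        xs = _payloads(dataset)
        out = np.empty(len(xs))
        for i, x in enumerate(xs):
            out[i] = self_information(model, x)
            if model.unobserved(x):
                flagged.append(i)
        return out, flagged
    raise PrismError("unknown-operator", op)


def tensor_representation(
    dataset: Sequence,
    models: Sequence,
    operators: Sequence[str],
) -> SpectrumTensor:
    """Tensorially combine a model panel with an operator panel.

    Every (operator, model) pairing is validated against
    :data:`OPERATOR_KINDS` first; a rank operator paired with a probability
    model, say, raises ``operator-model-kind-mismatch``.
    """
    if len(dataset) == 0:
        raise PrismError("empty-dataset", "tensor_representation")
    for op in operators:
        if op not in OPERATOR_KINDS:
            raise PrismError("unknown-operator", op)
        need = OPERATOR_KINDS[op]
        for model in models:
            if need is not None and getattr(model, "kind", None) != need:
                raise PrismError(
                    "operator-model-kind-mismatch",
                    f"operator {op!r} needs a {need} model, "
                    f"got {getattr(model, 'kind', type(model).__name__)!r} "
                    f"({getattr(model, 'id', '?')})",
                )
    ids = _ids(dataset)
    values = np.empty((len(dataset), len(models), len(operators)))
    flags: set = set()
    for j, model in enumerate(models):
        for k, op in enumerate(operators):
            vec, flagged = _apply_operator(op, dataset, model)
            values[:, j, k] = vec
            for i in flagged:
                flags.add((ids[i], model.id))
    return SpectrumTensor(
        element_ids=ids,
        model_ids=[m.id for m in models],
        operator_ids=list(operators),
        values=values,
        flags=flags,
    )


def spectrum_of(tensor: SpectrumTensor, element_id: str) -> Spectrum:
    """The spectrum of one element: a zero-copy row view of the tensor."""
    return tensor.spectrum_of(element_id)


def cospectrum_of(tensor: SpectrumTensor, model_id: str) -> CoSpectrum:
    """The co-spectrum of one model: a zero-copy column view of the tensor."""
    return tensor.cospectrum_of(model_id)
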