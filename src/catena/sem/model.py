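"""Declarative latent-variable model specification.

A model is a list of parameter entries over the union of observed and
latent variables.  Internally everything maps onto the reticular (RAM)
matrices: a directed-path matrix ``A`` (loadings and regressions), a
symmetric matrix ``S`` (variances and covariances of exogenous terms and
residuals) and a mean/intercept vector ``m``.  Shared labels impose
equality constraints, within and across groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

KINDS = ("loading", "regression", "covariance", "variance", "mean")


class ModelError(ValueError):
    """Raised for malformed or unidentified model specifications."""


@dataclass(frozen=True)
class Entry:
    """One parameter of the model.

    ``lhs``/``rhs`` follow the matrix convention: for a loading, ``lhs``
    is the indicator and ``rhs`` the latent; for a regression, ``lhs``
    is the outcome and ``rhs`` the predictor; for a (co)variance the two
    variables involved; for a mean, ``rhs`` is ignored.
    ``group`` of ``None`` means the entry applies to every group.  A
    shared explicit ``label`` ties the parameter across entries (and
    across groups); without a label, an all-group free entry is expanded
    to one independent parameter per group.
    """

    kind: str
    lhs: str
    rhs: str = ""
    free: bool = True
    value: float = 0.0
    start: float | None = None
    label: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ModelError(f"unknown entry kind {self.kind!r}")


@dataclass
class ModelSpec:
    observed: list[str]
    latent: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=lambda: ["all"])
    entries: list[Entry] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add(self, kind: str, lhs: str, rhs: str = "", **kw) -> None:
        self.entries.append(Entry(kind, lhs, rhs, **kw))

    @property
    def variables(self) -> list[str]:
        return list(self.observed) + list(self.latent)

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            observed=list(self.observed),
            latent=list(self.latent),
            groups=list(self.groups),
            entries=list(self.entries),
        )

    # -- constraint surgery ---------------------------------------------------

    def fix(self, label: str, value: float = 0.0) -> "ModelSpec":
        """Return a copy with every entry carrying ``label`` fixed to ``value``."""
        out = self.copy()
        hit = False
        out.entries = [
            replace(e, free=False, value=value) if e.label == label else e
            for e in out.entries
        ]
        hit = any(e.label == label for e in self.entries)
        if not hit:
            raise ModelError(f"no entry labelled {label!r}")
        return out

    def constrain_equal(self, labels: Sequence[str], shared: str) -> "ModelSpec":
        """Return a copy where all ``labels`` share one parameter ``shared``."""
        wanted = set(labels)
        found = {e.label for e in self.entries if e.label in wanted}
        missing = wanted - found
        if missing:
            raise ModelError(f"labels not in model: {sorted(missing)}")
        out = self.copy()
        out.entries = [
            replace(e, label=shared) if e.label in wanted else e
            for e in out.entries
        ]
        return out

    def labels_of_kind(self, kind: str, group: str | None = None) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.kind != kind or not e.free or e.label is None:
                continue
            if group is not None and e.group not in (None, group):
                continue
            if e.label not in seen:
                seen.append(e.label)
        return seen

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        names = set(self.variables)
        if len(names) != len(self.variables):
            raise ModelError("duplicate variable names")
        for e in self.entries:
            if e.lhs not in names:
                raise ModelError(f"unknown variable {e.lhs!r} in entry {e}")
            if e.kind != "mean" and e.rhs not in names:
                raise ModelError(f"unknown variable {e.rhs!r} in entry {e}")
            if e.group is not None and e.group not in self.groups:
                raise ModelError(f"unknown group {e.group!r}")
        self._check_duplicates()
        self._check_scale_constraints()
        self._check_acyclic()

    def _check_duplicates(self) -> None:
        for g in self.groups:
            seen = set()
            for e in self._group_entries(g):
                if e.kind in ("covariance", "variance"):
                    key = (("covariance"),) + tuple(sorted((e.lhs, e.rhs or e.lhs)))
                elif e.kind == "mean":
                    key = ("mean", e.lhs)
                else:
                    key = ("path", e.lhs, e.rhs)
                if key in seen:
                    raise ModelError(f"duplicate entry {key} in group {g!r}")
                seen.add(key)

    def _check_scale_constraints(self) -> None:
        for g in self.groups:
            entries = self._group_entries(g)
            for lv in self.latent:
                fixed_loading = sum(
                    1
                    for e in entries
                    if e.kind == "loading" and e.rhs == lv and not e.free
                )
                fixed_var = any(
                    e.kind == "variance" and e.lhs == lv and not e.free
                    for e in entries
                )
                is_endogenous = any(
                    e.kind == "regression" and e.lhs == lv for e in entries
                )
                if fixed_loading + fixed_var == 0 and not is_endogenous:
                    raise ModelError(
                        f"latent {lv!r} has no scale constraint in group {g!r}"
                    )
                if fixed_loading >= 1 and fixed_var:
                    raise ModelError(
                        f"latent {lv!r} has redundant scale constraints in group {g!r}"
                    )

    def _check_acyclic(self) -> None:
        # directed edges rhs -> lhs over all groups
        edges: dict[str, set[str]] = {v: set() for v in self.variables}
        for e in self.entries:
            if e.kind in ("loading", "regression"):
                edges[e.rhs].add(e.lhs)
        state: dict[str, int] = {}

        def visit(v: str) -> None:
            state[v] = 1
            for w in edges[v]:
                s = state.get(w, 0)
                if s == 1:
                    raise ModelError(f"cyclic directed paths involving {v!r}")
                if s == 0:
                    visit(w)
            state[v] = 2

        for v in self.variables:
            if state.get(v, 0) == 0:
                visit(v)

    def _group_entries(self, group: str) -> list[Entry]:
        return [e for e in self.entries if e.group in (None, group)]

    # -- parameter table ------------------------------------------------------

    def parameter_table(self) -> "ParameterTable":
        """Expand entries into per-group matrix placements."""
        self.validate()
        return ParameterTable(self)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "latent": self.latent,
            "groups": self.groups,
            "entries": [
                {
                    "kind": e.kind,
                    "lhs": e.lhs,
                    "rhs": e.rhs,
                    "free": e.free,
                    "value": e.value,
                    "start": e.start,
                    "label": e.label,
                    "group": e.group,
                }
                for e in self.entries
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(
            observed=list(d["observed"]),
            latent=list(d.get("latent", [])),
            groups=list(d.get("groups", ["all"])),
        )
        for ed in d.get("entries", []):
            spec.entries.append(Entry(**ed))
        return spec

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class ParameterTable:
    """Placement map from free-parameter vector to RAM matrices.

    Attributes
    ----------
    labels : ordered free-parameter labels (one optimisation coordinate each)
    placements : label -> list of (group index, matrix ∈ {A,S,m}, i, j)
    fixed : list of (group index, matrix, i, j, value)
    is_variance : per label, True when the label touches any diagonal S entry
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.var_index = {v: i for i, v in enumerate(spec.variables)}
        self.n_vars = len(spec.variables)
        self.n_obs = len(spec.observed)
        self.labels: list[str] = []
        self.placements: dict[str, list[tuple[int, str, int, int]]] = {}
        self.fixed: list[tuple[int, str, int, int, float]] = []
        self.starts: dict[str, float] = {}
        self.is_variance: dict[str, bool] = {}

        for gi, g in enumerate(spec.groups):
            for e in spec._group_entries(g):
                mat, i, j = self._locate(e)
                if not e.free:
                    self.fixed.append((gi, mat, i, j, e.value))
                    continue
                label = e.label or self._auto_label(e, g)
                if label not in self.placements:
                    self.labels.append(label)
                    self.placements[label] = []
                    self.is_variance[label] = False
                self.placements[label].append((gi, mat, i, j))
                if mat == "S" and i == j:
                    self.is_variance[label] = True
                if e.start is not None:
                    self.starts[label] = e.start

    @staticmethod
    def _auto_label(e: Entry, group: str) -> str:
        core = f"{e.kind}:{e.lhs}" + (f"~{e.rhs}" if e.kind != "mean" else "")
        return f"{core}@{group}"

    def _locate(self, e: Entry) -> tuple[str, int, int]:
        i = self.var_index[e.lhs]
        if e.kind == "mean":
            return "m", i, 0
        j = self.var_index[e.rhs]
        if e.kind in ("loading", "regression"):
            return "A", i, j
        return "S", i, j

    def n_free(self) -> int:
        return len(self.labels)

    def matrices(self, theta: np.ndarray) -> list[dict[str, np.ndarray]]:
        """Assemble per-group A, S, m for a parameter vector."""
        nv = self.n_vars
        out = [
            {"A": np.zeros((nv, nv)), "S": np.zeros((nv, nv)), "m": np.zeros(nv)}
            for _ in self.spec.groups
        ]
        for gi, mat, i, j, value in self.fixed:
            self._put(out[gi], mat, i, j, value)
        for k, label in enumerate(self.labels):
            for gi, mat, i, j in self.placements[label]:
                self._put(out[gi], mat, i, j, theta[k])
        return out

    @staticmethod
    def _put(mats: dict[str, np.ndarray], mat: str, i: int, j: int, v: float) -> None:
        if mat == "m":
            mats["m"][i] = v
        elif mat == "A":
            mats["A"][i, j] = v
        else:
            mats["S"][i, j] = v
            mats["S"][j, i] = v
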