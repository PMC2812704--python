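"""Domain types and text-file I/O for ward-level psychosis-duration data.

The observational unit is an individual with a first episode of psychosis;
the grouping unit is the electoral ward of residence.  The response used
throughout the package is the natural logarithm of the duration of
untreated psychosis (DUP, recorded in days).  Covariates are age in years,
sex, and a seven-category ethnicity coded as six dummy contrasts against a
white British baseline.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ETHNICITY_LEVELS = (
    "white_british",
    "other_white",
    "black_caribbean",
    "black_african",
    "asian",
    "mixed",
    "other",
)
BASELINE_ETHNICITY = "white_british"
SEX_LEVELS = ("female", "male")  # male is coded 1 in the design matrix
DIAGNOSIS_LEVELS = ("nonaffective", "affective")

#: Column order of the full design matrix (fixed so fitted-model reports are
#: directly comparable across runs).
COVARIATE_NAMES = (
    "age",
    "sex_male",
    "other_white",
    "black_caribbean",
    "black_african",
    "asian",
    "mixed",
    "other",
)

_ETHNICITY_ALIASES = {
    "white_british": "white_british",
    "british": "white_british",
    "other_white": "other_white",
    "white_other": "other_white",
    "black_caribbean": "black_caribbean",
    "black_african": "black_african",
    "asian": "asian",
    "asian_indian_subcontinent": "asian",
    "mixed": "mixed",
    "mixed_ethnicity": "mixed",
    "mixed_ethnicities": "mixed",
    "other": "other",
    "other_ethnic_groups": "other",
    "other_ethnicities": "other",
}

_SEX_ALIASES = {
    "male": "male", "m": "male", "man": "male", "men": "male",
    "female": "female", "f": "female", "woman": "female", "women": "female",
}


def _norm(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(label).strip().lower()).strip("_")


def _parse_sex(value: str, row: object = None) -> str:
    key = _norm(value)
    if key not in _SEX_ALIASES:
        raise ValueError(f"unknown sex label {value!r} (row {row})")
    return _SEX_ALIASES[key]


def _parse_ethnicity(value: str, row: object = None) -> str:
    key = _norm(value)
    if key not in _ETHNICITY_ALIASES:
        raise ValueError(
            f"unknown ethnicity label {value!r} (row {row}); "
            f"expected one of {ETHNICITY_LEVELS}"
        )
    return _ETHNICITY_ALIASES[key]


def _parse_diagnosis(value: Optional[str], row: object = None) -> Optional[str]:
    if value is None:
        return None
    key = _norm(value)
    if key in ("", "na", "nan", "none"):
        return None
    if key in ("nonaffective", "non_affective", "f20_29", "f20_f29"):
        return "nonaffective"
    if key in ("affective", "f30_33", "f30_f33"):
        return "affective"
    m = re.fullmatch(r"f(\d{2})(?:_\d+)?", key)
    if m:
        code = int(m.group(1))
        if 20 <= code <= 29:
            return "nonaffective"
        if 30 <= code <= 33:
            return "affective"
    raise ValueError(f"unknown diagnosis label {value!r} (row {row})")


@dataclass(frozen=True)
class IndividualRecord:
    """One analysed case: ward of residence, raw DUP and covariates."""

    ward_id: str
    dup_days: float
    age: float
    sex: str
    ethnicity: str
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ward_id:
            raise ValueError("ward_id must be non-empty")
        if not np.isfinite(self.dup_days) or self.dup_days <= 0:
            raise ValueError(f"dup_days must be positive, got {self.dup_days}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise ValueError(
                f"ethnicity must be one of {ETHNICITY_LEVELS}, got {self.ethnicity!r}"
            )
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSIS_LEVELS:
            raise ValueError(f"diagnosis must be in {DIAGNOSIS_LEVELS} or None")


class RecordList(list):
    """List of :class:`IndividualRecord` that remembers how many input rows
    were rejected (missing ward assignment)."""

    n_rejected: int = 0


@dataclass
class WardGraph:
    """Symmetric ward contiguity structure.

    ``wards`` is the ordered list of ward labels (length K); ``neighbours[i]``
    is the sorted tuple of 0-based indices adjacent to ward i.
    """

    wards: tuple
    neighbours: tuple

    def __post_init__(self) -> None:
        self.wards = tuple(str(w) for w in self.wards)
        if len(self.wards) < 1:
            raise ValueError("graph needs at least one ward")
        if len(set(self.wards)) != len(self.wards):
            raise ValueError("duplicate ward labels")
        for w in self.wards:
            if re.search(r"\s", w):
                raise ValueError(f"ward label {w!r} contains whitespace")
        K = len(self.wards)
        nb = []
        for i, ns in enumerate(self.neighbours):
            ns = tuple(sorted(int(j) for j in ns))
            if i in ns:
                raise ValueError(f"self-loop at ward {self.wards[i]!r}")
            if any(j < 0 or j >= K for j in ns):
                raise ValueError(f"neighbour index out of range for ward {self.wards[i]!r}")
            if len(set(ns)) != len(ns):
                raise ValueError(f"duplicate neighbour for ward {self.wards[i]!r}")
            nb.append(ns)
        if len(nb) != K:
            raise ValueError("neighbours must have one entry per ward")
        for i, ns in enumerate(nb):
            for j in ns:
                if i not in nb[j]:
                    raise ValueError(
                        f"adjacency not symmetric: {self.wards[i]!r} -> {self.wards[j]!r}"
                    )
        self.neighbours = tuple(nb)

    # -- basic properties -------------------------------------------------
    @property
    def n_wards(self) -> int:
        return len(self.wards)

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.array([len(ns) for ns in self.neighbours], dtype=int)

    @cached_property
    def index(self) -> dict:
        return {w: i for i, w in enumerate(self.wards)}

    @cached_property
    def edges(self) -> tuple:
        """Each undirected edge once, as (i, j) with i < j."""
        return tuple(
            (i, j) for i, ns in enumerate(self.neighbours) for j in ns if i < j
        )

    @cached_property
    def component_labels(self) -> np.ndarray:
        """Connected-component label per ward (BFS)."""
        K = self.n_wards
        labels = np.full(K, -1, dtype=int)
        comp = 0
        for start in range(K):
            if labels[start] >= 0:
                continue
            q = deque([start])
            labels[start] = comp
            while q:
                u = q.popleft()
                for v in self.neighbours[u]:
                    if labels[v] < 0:
                        labels[v] = comp
                        q.append(v)
            comp += 1
        return labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def laplacian(self) -> np.ndarray:
        K = self.n_wards
        L = np.zeros((K, K))
        for i, j in self.edges:
            L[i, i] += 1.0
            L[j, j] += 1.0
            L[i, j] -= 1.0
            L[j, i] -= 1.0
        return L

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable, wards: Optional[Sequence[str]] = None) -> "WardGraph":
        edges = [(str(a), str(b)) for a, b in edges]
        if wards is None:
            seen: dict = {}
            for a, b in edges:
                seen.setdefault(a, None)
                seen.setdefault(b, None)
            wards = list(seen)
        wards = [str(w) for w in wards]
        idx = {w: i for i, w in enumerate(wards)}
        nb = [set() for _ in wards]
        for a, b in edges:
            if a not in idx or b not in idx:
                missing = {w for w in (a, b) if w not in idx}
                raise ValueError(f"edge ward(s) not in ward list: {sorted(missing)}")
            if a == b:
                raise ValueError(f"self-loop at ward {a!r}")
            nb[idx[a]].add(idx[b])
            nb[idx[b]].add(idx[a])
        return cls(tuple(wards), tuple(tuple(sorted(s)) for s in nb))

    def subgraph(self, keep: Sequence[str]) -> "WardGraph":
        """Induced subgraph on the given ward labels (order preserved)."""
        keep = [str(w) for w in keep]
        missing = [w for w in keep if w not in self.index]
        if missing:
            raise ValueError(f"wards not in graph: {missing}")
        old = [self.index[w] for w in keep]
        remap = {o: n for n, o in enumerate(old)}
        nb = tuple(
            tuple(sorted(remap[j] for j in self.neighbours[o] if j in remap))
            for o in old
        )
        return WardGraph(tuple(keep), nb)


# ---------------------------------------------------------------------------
# Adjacency file dialects
# ---------------------------------------------------------------------------

_WARD_HEADER = re.compile(r"^#\s*wards\s*:\s*(.*)$")


def _read_ward_header(lines: list) -> tuple:
    """Pop an optional '# wards: a b c' header; return (ward list or None, rest)."""
    body = [ln for ln in lines if ln.strip()]
    if body and (m := _WARD_HEADER.match(body[0].strip())):
        return m.group(1).split(), body[1:]
    return None, body


def load_adjacency(path, format: str = "edge_list",
                   ward_ids: Optional[Sequence[str]] = None,
                   encoding: str = "utf-8") -> WardGraph:
    """Read a ward contiguity graph.

    ``format='edge_list'``: one ``ward_a<TAB>ward_b`` pair per line.
    ``format='geobugs'``: a ward-count line then, per ward, its neighbour
    count followed by 1-based neighbour indices.  Either dialect may start
    with a ``# wards: ...`` header naming the wards in order.
    """
    with open(path, encoding=encoding) as fh:
        lines = fh.readlines()
    header_wards, body = _read_ward_header(lines)
    if ward_ids is not None:
        header_wards = [str(w) for w in ward_ids]

    if format == "edge_list":
        edges = []
        for ln in body:
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {ln.strip()!r}")
            edges.append((parts[0], parts[1]))
        return WardGraph.from_edges(edges, wards=header_wards)

    if format == "geobugs":
        if not body:
            raise ValueError("empty adjacency file")
        K = int(body[0].split()[0])
        if len(body) - 1 != K:
            raise ValueError(f"expected {K} ward lines, found {len(body) - 1}")
        wards = header_wards or [f"ward_{i + 1}" for i in range(K)]
        if len(wards) != K:
            raise ValueError("ward name list length does not match ward count")
        nb = []
        for i, ln in enumerate(body[1:]):
            nums = [int(t) for t in ln.split()]
            count, idxs = nums[0], nums[1:]
            if len(idxs) != count:
                raise ValueError(f"ward line {i + 1}: declared {count} neighbours, "
                                 f"listed {len(idxs)}")
            zero_based = []
            for j in idxs:
                if not (1 <= j <= K):
                    raise ValueError(f"ward line {i + 1}: neighbour index {j} out of range")
                zero_based.append(j - 1)
            nb.append(tuple(sorted(zero_based)))
        # WardGraph.__post_init__ enforces symmetry / no self-loops
        return WardGraph(tuple(wards), tuple(nb))

    raise ValueError(f"unknown adjacency format {format!r}")


def save_adjacency(graph: WardGraph, path, format: str = "edge_list",
                   encoding: str = "utf-8") -> None:
    lines = [f"# wards: {' '.join(graph.wards)}\n"]
    if format == "edge_list":
        for i, j in graph.edges:
            lines.append(f"{graph.wards[i]}\t{graph.wards[j]}\n")
    elif format == "geobugs":
        lines.append(f"{graph.n_wards}\n")
        for ns in graph.neighbours:
            lines.append(" ".join([str(len(ns))] + [str(j + 1) for j in ns]) + "\n")
    else:
        raise ValueError(f"unknown adjacency format {format!r}")
    with open(path, "w", encoding=encoding) as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------

def load_individuals(path, sep: str = ",", zero_offset: bool = False,
                     encoding: str = "utf-8") -> RecordList:
    """Read individual-level records from delimited text.

    Required columns: ward_id, dup_days, age, sex, ethnicity; optional:
    diagnosis.  Rows with a missing ward assignment are rejected (count kept
    on the returned list and logged), mirroring the exclusion of cases whose
    address could not be established.  A DUP of zero days is an error unless
    ``zero_offset`` is set, in which case it is replaced by half a day.
    """
    df = pd.read_csv(path, sep=sep, encoding=encoding, dtype=str,
                     skipinitialspace=True)
    required = {"ward_id", "dup_days", "age", "sex", "ethnicity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    has_dx = "diagnosis" in df.columns

    out = RecordList()
    rejected = 0
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        ward = getattr(row, "ward_id")
        if ward is None or (isinstance(ward, float) and np.isnan(ward)) \
                or str(ward).strip() == "" or str(ward).lower() == "nan":
            rejected += 1
            continue
        dup = float(getattr(row, "dup_days"))
        if dup == 0.0:
            if not zero_offset:
                raise ValueError(
                    f"dup_days is 0 at line {pos}; enable zero_offset to "
                    "replace zero durations with 0.5 days"
                )
            logger.info("line %d: dup_days 0 replaced by 0.5 (zero_offset)", pos)
            dup = 0.5
        elif dup < 0:
            raise ValueError(f"negative dup_days at line {pos}")
        out.append(IndividualRecord(
            ward_id=str(ward).strip(),
            dup_days=dup,
            age=float(getattr(row, "age")),
            sex=_parse_sex(getattr(row, "sex"), pos),
            ethnicity=_parse_ethnicity(getattr(row, "ethnicity"), pos),
            diagnosis=_parse_diagnosis(getattr(row, "diagnosis"), pos) if has_dx else None,
        ))
    out.n_rejected = rejected
    if rejected:
        logger.warning("rejected %d row(s) with missing ward assignment", rejected)
    return out


def write_individuals(records: Sequence[IndividualRecord], path,
                      sep: str = ",", encoding: str = "utf-8") -> None:
    df = pd.DataFrame(
        {
            "ward_id": [r.ward_id for r in records],
            "dup_days": [r.dup_days for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "diagnosis": [r.diagnosis if r.diagnosis is not None else "" for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False, encoding=encoding)


def log_transform(records, zero_offset: bool = False) -> np.ndarray:
    """Natural log of DUP in days, order preserved.

    Accepts a sequence of records or a numeric array.  Non-positive values
    raise unless ``zero_offset`` replaces exact zeros with half a day.
    """
    if len(records) and isinstance(records[0], IndividualRecord):
        x = np.array([r.dup_days for r in records], dtype=float)
    else:
        x = np.asarray(records, dtype=float)
    if zero_offset:
        x = np.where(x == 0.0, 0.5, x)
    if np.any(x <= 0):
        bad = int(np.flatnonzero(x <= 0)[0])
        raise ValueError(f"non-positive DUP at position {bad}")
    return np.log(x)


# ---------------------------------------------------------------------------
# Model forms and the design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which blocks enter the linear predictor.

    The six standard forms of the model ladder:

    ======  ==========  ============  =========
    label   covariates  unstructured  spatial
    ======  ==========  ============  =========
    model1      no          yes           no
    model2      yes         yes           no
    model3      yes         no            no
    model4      no          no            yes
    model5      yes         no            yes
    model6      yes         yes           yes
    ======  ==========  ============  =========
    """

    include_covariates: bool
    include_unstructured: bool
    include_spatial: bool
    label: str = "custom"


MODEL_LADDER = (
    ModelSpec(False, True, False, "model1"),
    ModelSpec(True, True, False, "model2"),
    ModelSpec(True, False, False, "model3"),
    ModelSpec(False, False, True, "model4"),
    ModelSpec(True, False, True, "model5"),
    ModelSpec(True, True, True, "model6"),
)
_LADDER_BY_LABEL = {m.label: m for m in MODEL_LADDER}


def model_spec(label: str) -> ModelSpec:
    """Look up one of the six standard model forms by label."""
    try:
        return _LADDER_BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown model label {label!r}; "
                         f"expected one of {sorted(_LADDER_BY_LABEL)}") from None


def design_matrix(records: Sequence[IndividualRecord],
                  center_age: bool = False) -> np.ndarray:
    """n x 8 covariate matrix in :data:`COVARIATE_NAMES` order.

    Ethnicity is coded as six 0/1 dummies against the white British
    baseline (all six zero).  Age enters untransformed by default so
    coefficients read as change in expected log-DUP per year.
    """
    n = len(records)
    X = np.zeros((n, len(COVARIATE_NAMES)))
    eth_col = {e: k + 2 for k, e in enumerate(ETHNICITY_LEVELS[1:])}
    for r_i, rec in enumerate(records):
        X[r_i, 0] = rec.age
        X[r_i, 1] = 1.0 if rec.sex == "male" else 0.0
        if rec.ethnicity != BASELINE_ETHNICITY:
            X[r_i, eth_col[rec.ethnicity]] = 1.0
    if center_age:
        X[:, 0] -= X[:, 0].mean()
    return X


@dataclass
class Dataset:
    """Aligned response, ward index and (optional) covariates."""

    response: np.ndarray          # log-DUP per individual
    ward_index: np.ndarray        # 0-based index into the graph's ward order
    covariates: Optional[np.ndarray]  # n x 8 or None
    n_per_ward: np.ndarray        # cases per ward, length K
    ward_ids: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.ward_index = np.asarray(self.ward_index, dtype=int)
        n = self.response.shape[0]
        if self.ward_index.shape[0] != n:
            raise ValueError("response and ward_index lengths differ")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape != (n, len(COVARIATE_NAMES)):
                raise ValueError(
                    f"covariates must be n x {len(COVARIATE_NAMES)}"
                )
        self.n_per_ward = np.asarray(self.n_per_ward, dtype=int)
        K = self.n_per_ward.shape[0]
        if n and (self.ward_index.min() < 0 or self.ward_index.max() >= K):
            raise ValueError("ward_index out of range")
        if int(self.n_per_ward.sum()) != n:
            raise ValueError("n_per_ward does not sum to the number of rows")

    @property
    def n_obs(self) -> int:
        return self.response.shape[0]

    @property
    def n_wards(self) -> int:
        return self.n_per_ward.shape[0]


def build_dataset(records: Sequence[IndividualRecord], graph: WardGraph,
                  spec: Optional[ModelSpec] = None,
                  zero_offset: bool = False,
                  center_age: bool = False) -> Dataset:
    """Assemble the modelling dataset against a ward graph.

    Wards present in the graph but without cases are retained (they still
    carry a spatial effect and contribute smoothing); use
    :func:`restrict_to_observed` first for the stricter convention of
    dropping case-free wards from the analysis.
    """
    missing = sorted({r.ward_id for r in records} - set(graph.wards))
    if missing:
        raise ValueError(f"record ward(s) not in graph: {missing}")
    y = log_transform(records, zero_offset=zero_offset)
    w = np.array([graph.index[r.ward_id] for r in records], dtype=int)
    X = None
    if spec is None or spec.include_covariates:
        X = design_matrix(records, center_age=center_age)
    counts = np.bincount(w, minlength=graph.n_wards)
    return Dataset(y, w, X, counts, ward_ids=graph.wards)


def restrict_to_observed(graph: WardGraph,
                         records: Sequence[IndividualRecord]) -> WardGraph:
    """Drop wards with no cases from the graph (kept ward order preserved)."""
    observed = {r.ward_id for r in records}
    keep = [w for w in graph.wards if w in observed]
    if not keep:
        raise ValueError("no ward has any cases")
    return graph.subgraph(keep)
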