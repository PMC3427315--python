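"""Morphological line of evidence.

Handles a specimen-by-character matrix with typed columns (metric
measurements in mm, meristic counts, qualitative states), runs MANOVA with
pairwise Hotelling T-squared tests and canonical variates analysis (CVA)
across island populations, detects fixed diagnostic character states
between groups, and offers the 75% rule as a quantitative diagnosability
criterion for subspecies.

Character typing lives in the CSV header, not in code: a column header is
``name|type`` or ``name|type|flag;flag`` with ``type`` one of ``metric``,
``meristic``, ``qualitative`` and flags drawn from ``graded`` and
``sex-limited``.  Flagged characters (e.g. graded male coloration) are
excluded from diagnosis by default.  Bilateral meristic characters are
stored as ``NAME_L`` / ``NAME_R`` columns and averaged on demand.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import SchemaError

logger = logging.getLogger(__name__)

CHARACTER_TYPES = {"metric", "meristic", "qualitative"}
CHARACTER_FLAGS = {"graded", "sex-limited"}
RESERVED = ("specimen_id", "population", "sex")

#: two-sided 99% central interval half-width of the standard normal
Z_99 = float(stats.norm.ppf(0.995))


@dataclass
class MorphMatrix:
    """Typed specimen x character table.

    ``data`` is indexed by specimen ID and carries ``population`` and
    ``sex`` columns plus one column per character (plain names, header
    tags stripped).
    """

    data: pd.DataFrame
    char_types: dict
    char_flags: dict

    def __post_init__(self):
        for col in ("population",):
            if col not in self.data.columns:
                raise SchemaError(f"missing required column {col!r}")
        for name, t in self.char_types.items():
            if t not in CHARACTER_TYPES:
                raise SchemaError(f"{name}: unknown character type {t!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def specimens(self) -> list:
        return list(self.data.index)

    @property
    def populations(self) -> pd.Series:
        return self.data["population"]

    def characters(self, ctype: Optional[str] = None) -> list:
        return [c for c, t in self.char_types.items()
                if ctype is None or t == ctype]

    def numeric_characters(self) -> list:
        """Metric and meristic characters, bilateral pairs reduced to their
        base name."""
        out, seen = [], set()
        for c in self.characters():
            if self.char_types[c] == "qualitative":
                continue
            base = c[:-2] if c.endswith(("_L", "_R")) else c
            if base not in seen:
                seen.add(base)
                out.append(base)
        return out

    def is_flagged(self, name: str) -> bool:
        base_cols = [c for c in (f"{name}_L", f"{name}_R", name)
                     if c in self.char_types]
        return any(self.char_flags.get(c) for c in base_cols)

    def character_type(self, name: str) -> str:
        if name in self.char_types:
            return self.char_types[name]
        if f"{name}_L" in self.char_types:
            return self.char_types[f"{name}_L"]
        raise KeyError(name)

    def values(self, name: str) -> pd.Series:
        """Column by base name; bilateral pairs return the left/right mean."""
        if name in self.data.columns:
            return self.data[name]
        left, right = f"{name}_L", f"{name}_R"
        if left in self.data.columns and right in self.data.columns:
            return self.data[[left, right]].mean(axis=1).rename(name)
        raise KeyError(name)

    def numeric_table(self, characters: Sequence) -> pd.DataFrame:
        return pd.concat([self.values(c) for c in characters], axis=1)

    def group_labels(self, grouping: Optional[Mapping] = None) -> pd.Series:
        """Specimen -> group; ``grouping`` maps populations onto coarser
        groups (clades), default is the population itself."""
        pops = self.populations
        if grouping is None:
            return pops
        return pops.map(lambda p: grouping.get(p, p))

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = self.data.copy()
        rename = {}
        for c in df.columns:
            if c in RESERVED:
                continue
            tag = f"{c}|{self.char_types[c]}"
            if self.char_flags.get(c):
                tag += "|" + ";".join(sorted(self.char_flags[c]))
            rename[c] = tag
        df = df.rename(columns=rename)
        df.index.name = "specimen_id"
        df.to_csv(path)


def read_morph_matrix(source) -> MorphMatrix:
    """Parse a morphology CSV whose header declares character types."""
    df = pd.read_csv(source)
    if df.empty:
        raise SchemaError("morphology table has no data rows")
    types: dict = {}
    flags: dict = {}
    rename: dict = {}
    for col in df.columns:
        parts = [p.strip() for p in col.split("|")]
        name = parts[0]
        if name in RESERVED:
            if len(parts) > 1:
                raise SchemaError(f"reserved column {name!r} must not be typed")
            continue
        if len(parts) < 2:
            raise SchemaError(f"column {col!r}: missing type tag (name|type)")
        ctype = parts[1]
        if ctype not in CHARACTER_TYPES:
            raise SchemaError(f"column {col!r}: unknown type tag {ctype!r}")
        fl = frozenset(f.strip() for f in parts[2].split(";")) if len(parts) > 2 \
            else frozenset()
        bad = fl - CHARACTER_FLAGS
        if bad:
            raise SchemaError(f"column {col!r}: unknown flags {sorted(bad)}")
        types[name] = ctype
        flags[name] = fl
        rename[col] = name
    if "specimen_id" not in df.columns:
        raise SchemaError("missing specimen_id column")
    df = df.rename(columns=rename).set_index("specimen_id")
    for name, t in types.items():
        if t in {"metric", "meristic"}:
            try:
                df[name] = pd.to_numeric(df[name])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {name!r}: non-numeric entry ({exc})")
        else:
            df[name] = df[name].astype("object").where(df[name].notna(), None)
            df[name] = df[name].map(lambda v: None if v is None else str(v))
    return MorphMatrix(data=df, char_types=types, char_flags=flags)


# ---------------------------------------------------------------------------
# multivariate tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df: tuple
    overall_p: float
    pairwise: Mapping   # (groupA, groupB) sorted -> p-value or None
    pairwise_notes: Mapping
    n_used: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "wilks_lambda": self.wilks_lambda,
            "F": self.f_stat,
            "df": list(self.df),
            "overall_p": self.overall_p,
            "pairwise_p": {"|".join(k): v for k, v in self.pairwise.items()},
            "pairwise_notes": {"|".join(k): v
                               for k, v in self.pairwise_notes.items()},
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }


def _sscp(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    return c.T @ c


def _complete_cases(mm: MorphMatrix, characters: Sequence,
                    grouping: Optional[Mapping]):
    x = mm.numeric_table(characters)
    groups = mm.group_labels(grouping)
    keep = x.notna().all(axis=1) & groups.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d incomplete specimens", dropped)
    return x[keep].to_numpy(float), groups[keep], dropped


def wilks_manova(x: np.ndarray, labels: np.ndarray):
    """Wilks' lambda with Rao's F approximation.

    Returns (lambda, F, (df1, df2), p).  Exact for p <= 2 or <= 3 groups.
    """
    groups = np.unique(labels)
    g, (n, p) = len(groups), x.shape
    if g < 2:
        raise ValueError("need >= 2 groups")
    if n - g < p:
        raise ValueError("too few complete specimens for covariance estimation")
    w = sum(_sscp(x[labels == lab]) for lab in groups)
    t = _sscp(x)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(t)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular scatter matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)
    df1 = p * (g - 1)
    denom = p ** 2 + (g - 1) ** 2 - 5
    s = np.sqrt((p ** 2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    mm_ = n - 1 - (p + g) / 2
    df2 = mm_ * s - df1 / 2 + 1
    lam_s = lam ** (1 / s)
    f = (1 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2))
    return lam, float(f), (df1, float(df2)), pval


def hotelling_t2(xa: np.ndarray, xb: np.ndarray):
    """Two-sample Hotelling T-squared with its F transform.

    Returns (T2, F, (df1, df2), p).  With one variable this reduces exactly
    to the squared two-sample t statistic.
    """
    na, nb = len(xa), len(xb)
    p = xa.shape[1]
    if na + nb - 2 < p:
        raise ValueError("too few specimens for pooled covariance")
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    s_pooled = (_sscp(xa) + _sscp(xb)) / (na + nb - 2)
    try:
        sol = np.linalg.solve(s_pooled, diff)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance")
    t2 = float(na * nb / (na + nb) * diff @ sol)
    df2 = na + nb - p - 1
    if df2 <= 0:
        raise ValueError("too few specimens for the F transform")
    f = t2 * df2 / (p * (na + nb - 2))
    pval = float(stats.f.sf(f, p, df2))
    return t2, float(f), (p, df2), pval


def manova(mm: MorphMatrix, characters: Sequence,
           grouping: Optional[Mapping] = None) -> ManovaResult:
    """Overall Wilks MANOVA plus pairwise Hotelling tests across groups.

    Complete-case analysis: specimens missing any selected character are
    dropped (and counted).  Group pairs too small for a pooled covariance
    are reported as untestable rather than silently NA.
    """
    x, groups, dropped = _complete_cases(mm, characters, grouping)
    labels = groups.to_numpy()
    lam, f, df, pval = wilks_manova(x, labels)
    pairwise: dict = {}
    notes: dict = {}
    for a, b in itertools.combinations(sorted(np.unique(labels)), 2):
        xa, xb = x[labels == a], x[labels == b]
        try:
            _, _, _, p_ab = hotelling_t2(xa, xb)
            pairwise[(a, b)] = p_ab
            notes[(a, b)] = "ok"
        except ValueError as exc:
            pairwise[(a, b)] = None
            notes[(a, b)] = f"untestable: {exc}"
    return ManovaResult(lam, f, df, pval, pairwise, notes, len(x), dropped)


@dataclass(frozen=True)
class CvaResult:
    """Canonical variates: scores per specimen, raw coefficient loadings
    per character and axis, eigenvalues sorted descending.

    Axis signs and scaling follow a fixed convention (within-group variance
    of scores is 1; the largest-magnitude loading on each axis is positive);
    comparisons across software are meaningful by rank of |loading| only.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    regularized: bool = False

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "loadings": self.loadings.round(4).to_dict(),
            "regularized": self.regularized,
        }


def cva(mm: MorphMatrix, characters: Sequence,
        grouping: Optional[Mapping] = None) -> CvaResult:
    """Canonical variates analysis (multi-group discriminant ordination).

    Solves the generalized eigenproblem of between-group versus pooled
    within-group scatter; at most ``min(p, g - 1)`` non-trivial axes.  A
    singular within-group scatter is ridge-regularized with a warning.
    """
    x, groups, _ = _complete_cases(mm, characters, grouping)
    labels = groups.to_numpy()
    uniq = np.unique(labels)
    g, (n, p) = len(uniq), x.shape
    if g < 2:
        raise ValueError("need >= 2 groups")
    w = sum(_sscp(x[labels == lab]) for lab in uniq)
    t = _sscp(x)
    b = t - w
    w_cov = w / (n - g)
    regularized = False
    try:
        evals, evecs = linalg.eigh(b / (n - g), w_cov)
    except linalg.LinAlgError:
        regularized = True
        ridge = 1e-8 * np.trace(w_cov) / p * np.eye(p)
        logger.warning("singular within-group scatter; ridge-regularizing")
        evals, evecs = linalg.eigh(b / (n - g), w_cov + ridge)
    order = np.argsort(evals)[::-1]
    n_axes = min(p, g - 1)
    evals = np.clip(evals[order][:n_axes], 0, None)
    vecs = evecs[:, order][:, :n_axes]
    # scaling: unit pooled within-group variance per axis (eigh already
    # B-orthonormalizes); sign: largest |loading| positive
    for k in range(n_axes):
        i = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    axes = [f"CV{k + 1}" for k in range(n_axes)]
    scores = pd.DataFrame((x - x.mean(axis=0)) @ vecs,
                          index=groups.index, columns=axes)
    loadings = pd.DataFrame(vecs, index=list(characters), columns=axes)
    return CvaResult(scores, loadings, evals, regularized)


# ---------------------------------------------------------------------------
# diagnosability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmadonResult:
    fraction_outside: float
    passes: bool
    interval: tuple


def amadon_75(values_a: Sequence, values_b: Sequence,
              interval: str = "normal") -> AmadonResult:
    """75% rule: does >= 75% of sample A lie outside 99% of B's range?

    ``interval="normal"`` uses the central 99% interval of a normal fitted
    to B (mean +/- 2.576 sd), which is stabler than the raw range for tiny
    samples; ``interval="range"`` uses B's observed min/max.  Zero variance
    in B degenerates to a point interval.
    """
    a = np.asarray([v for v in values_a if v is not None and np.isfinite(v)],
                   float)
    b = np.asarray([v for v in values_b if v is not None and np.isfinite(v)],
                   float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    if interval == "normal":
        sd = b.std(ddof=1)
        lo, hi = b.mean() - Z_99 * sd, b.mean() + Z_99 * sd
    elif interval == "range":
        lo, hi = b.min(), b.max()
    else:
        raise ValueError(f"unknown interval mode {interval!r}")
    frac = float(np.mean((a < lo) | (a > hi)))
    return AmadonResult(frac, frac >= 0.75, (float(lo), float(hi)))


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-character diagnosability between two groups.

    Status is ``fixed-qualitative`` (observed state sets disjoint, both
    non-empty), ``quantitative-diagnosable`` (numeric criterion met),
    ``overlapping``, or ``excluded`` (graded / sex-limited flag applied).
    """

    group_a: str
    group_b: str
    records: Mapping  # character -> dict(status=..., detail=...)

    def diagnostic_characters(self) -> list:
        return [c for c, r in self.records.items()
                if r["status"] in {"fixed-qualitative",
                                   "quantitative-diagnosable"}]

    @property
    def has_diagnostic(self) -> bool:
        return bool(self.diagnostic_characters())

    def to_dict(self) -> dict:
        return {"group_a": self.group_a, "group_b": self.group_b,
                "characters": dict(self.records)}


def _group_mask(mm: MorphMatrix, group) -> pd.Series:
    pops = {group} if isinstance(group, str) else set(group)
    return mm.populations.isin(pops)


def fixed_diagnostic_characters(mm: MorphMatrix, group_a, group_b,
                                include_graded: bool = False,
                                quantitative: str = "range",
                                characters: Optional[Sequence] = None
                                ) -> DiagnosticReport:
    """Find characters with disjoint observed states between two groups.

    Groups are population labels or iterables of labels (clades).
    Qualitative characters are *fixed* iff the observed state sets are
    disjoint and both non-empty.  Numeric characters are diagnosable when
    observed ranges are disjoint (``quantitative="range"``) or when the 75%
    rule passes in either direction (``quantitative="amadon"``).  Characters
    flagged graded or sex-limited are excluded unless ``include_graded``.
    """
    mask_a, mask_b = _group_mask(mm, group_a), _group_mask(mm, group_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must contain specimens")
    names = list(characters) if characters is not None else (
        [c for c in mm.characters("qualitative")] + mm.numeric_characters())
    records: dict = {}
    for name in names:
        if mm.is_flagged(name) and not include_graded:
            records[name] = {"status": "excluded",
                             "detail": "graded/sex-limited flag"}
            continue
        vals = mm.values(name)
        va, vb = vals[mask_a].dropna(), vals[mask_b].dropna()
        if mm.character_type(name) == "qualitative":
            sa, sb = set(va), set(vb)
            if sa and sb and not (sa & sb):
                records[name] = {"status": "fixed-qualitative",
                                 "detail": {"states_a": sorted(sa),
                                            "states_b": sorted(sb)}}
            else:
                records[name] = {"status": "overlapping",
                                 "detail": {"shared": sorted(sa & sb)}}
        else:
            if len(va) == 0 or len(vb) == 0:
                records[name] = {"status": "overlapping",
                                 "detail": "missing in one group"}
                continue
            if quantitative == "range":
                disjoint = va.max() < vb.min() or vb.max() < va.min()
                detail = {"range_a": [float(va.min()), float(va.max())],
                          "range_b": [float(vb.min()), float(vb.max())]}
                ok = bool(disjoint)
            elif quantitative == "amadon":
                try:
                    r1 = amadon_75(va, vb)
                    r2 = amadon_75(vb, va)
                    ok = r1.passes or r2.passes
                    detail = {"fraction_outside": max(r1.fraction_outside,
                                                     r2.fraction_outside)}
                except ValueError:
                    ok, detail = False, "sample too small for 75% rule"
            else:
                raise ValueError(f"unknown quantitative mode {quantitative!r}")
            records[name] = {
                "status": "quantitative-diagnosable" if ok else "overlapping",
                "detail": detail,
            }
    ga = group_a if isinstance(group_a, str) else "+".join(sorted(group_a))
    gb = group_b if isinstance(group_b, str) else "+".join(sorted(group_b))
    return DiagnosticReport(ga, gb, records)
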