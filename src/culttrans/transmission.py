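"""Additive cultural transmission: parental types, coefficients and biases.

Following the additive transmission model, each network with at least one
parent and one friend is classified by the dichotomised traits of its
*Vertical* component (averaged parents) and *Horizontal* component
(averaged friends) into one of four **cultural parental types**:

======  ==============================  =======================
type    meaning                         expected adoption rate
======  ==============================  =======================
VH      parents and friends have trait  Other + Vertical + Horizontal
Vh      only parents have it            Other + Vertical
vH      only friends have it            Other + Horizontal
vh      neither has it                  Other
======  ==============================  =======================

With ``P_i`` networks of type ``i`` and ``N_i`` students having the
trait, the **transmission coefficient** ``B_i = N_i / P_i`` estimates the
cell's adoption probability.  The Vertical, Horizontal and Other *biases*
are fitted to the four cells by exhaustive grid search; because a student
without the trait has its opposite, the opposite-trait table is the
complement of the trait table under the type inversion VH<->vh, Vh<->vH,
and Vertical/Horizontal biases are shared between the two polarities
while each polarity has its own Other baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import NetworkTable, aggregate_components, dichotomize_scores

logger = logging.getLogger(__name__)

__all__ = [
    "PARENTAL_TYPES",
    "ParentalTypeTable",
    "BiasEstimate",
    "classify_parental_type",
    "transmission_table",
    "opposite_table",
    "bootstrap_ci",
    "estimate_biases",
    "triangle_coordinates",
    "OBJECTIVES",
]

PARENTAL_TYPES = ("VH", "Vh", "vH", "vh")
_INVERSE = {"VH": "vh", "vh": "VH", "Vh": "vH", "vH": "Vh"}
#: indicator of (has Vertical, has Horizontal) per type
_TYPE_VH = {"VH": (1, 1), "Vh": (1, 0), "vH": (0, 1), "vh": (0, 0)}

OBJECTIVES = ("binomial_loglik", "sse_proportions", "sse_counts")


def classify_parental_type(vertical_trait: int, horizontal_trait: int) -> str:
    """Map the (Vertical, Horizontal) trait pair to a parental type."""
    for name, t in (("vertical", vertical_trait), ("horizontal", horizontal_trait)):
        tv = getattr(t, "value", t)
        if tv is None or (isinstance(tv, float) and np.isnan(tv)):
            raise ValueError(
                f"{name} component undefined; filter networks with the "
                "parent_and_friend rule before classification"
            )
        if tv not in (0, 1):
            raise ValueError(f"{name} trait must be 0 or 1, got {t!r}")
    v = getattr(vertical_trait, "value", vertical_trait)
    h = getattr(horizontal_trait, "value", horizontal_trait)
    return ("V" if v else "v") + ("H" if h else "h")


@dataclass
class ParentalTypeTable:
    """Counts and transmission coefficients for one factor and polarity.

    ``data`` is indexed by parental type with columns ``P`` (networks),
    ``N`` (students with the trait), ``B`` (= N/P, NaN when P = 0) and,
    after :func:`bootstrap_ci`, ``ci_low``/``ci_high``.
    """

    factor: str
    polarity: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.polarity not in ("trait", "opposite"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        d = self.data
        if list(d.index) != list(PARENTAL_TYPES):
            d = d.reindex(PARENTAL_TYPES)
        if (d["N"] > d["P"]).any() or (d[["P", "N"]] < 0).any().any():
            raise ValueError("counts must satisfy 0 <= N <= P")
        d = d.copy()
        d["P"] = d["P"].astype(int)
        d["N"] = d["N"].astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            d["B"] = np.where(d["P"] > 0, d["N"] / d["P"].replace(0, 1), np.nan)
        self.data = d

    @classmethod
    def from_counts(
        cls,
        P: dict[str, int],
        N: dict[str, int],
        factor: str = "factor",
        polarity: str = "trait",
    ) -> "ParentalTypeTable":
        df = pd.DataFrame(
            {"P": [P[t] for t in PARENTAL_TYPES], "N": [N[t] for t in PARENTAL_TYPES]},
            index=list(PARENTAL_TYPES),
        )
        return cls(factor=factor, polarity=polarity, data=df)

    @property
    def P(self) -> pd.Series:
        return self.data["P"]

    @property
    def N(self) -> pd.Series:
        return self.data["N"]

    @property
    def B(self) -> pd.Series:
        return self.data["B"]

    @property
    def n_networks(self) -> int:
        return int(self.data["P"].sum())

    def to_dict(self) -> dict:
        out = {"factor": self.factor, "polarity": self.polarity, "types": {}}
        for t in PARENTAL_TYPES:
            row = self.data.loc[t]
            cell = {"P": int(row["P"]), "N": int(row["N"]),
                    "B": None if np.isnan(row["B"]) else float(row["B"])}
            for c in ("ci_low", "ci_high"):
                if c in self.data.columns:
                    cell[c] = None if np.isnan(row[c]) else float(row[c])
            out["types"][t] = cell
        return out


def _trait_indicators(
    table: NetworkTable, factor: str, threshold: float = 0.0
) -> pd.DataFrame:
    """Per-network dichotomised (student, vertical, horizontal) traits."""
    comp = aggregate_components(table)
    try:
        sub = comp.xs(factor, level="factor")
    except KeyError:
        raise ValueError(f"factor {factor!r} not present in table") from None
    if sub[["student", "vertical", "horizontal"]].isna().any().any():
        bad = sub[sub[["student", "vertical", "horizontal"]].isna().any(axis=1)]
        raise ValueError(
            f"{len(bad)} networks lack a student score, parent or friend for "
            f"{factor!r}; apply filter_networks('parent_and_friend') and "
            "impute_missing first"
        )
    out = pd.DataFrame(index=sub.index)
    for col in ("student", "vertical", "horizontal"):
        out[col] = dichotomize_scores(sub[col], threshold).astype(int)
    return out


def transmission_table(
    table: NetworkTable,
    factor: str,
    threshold: float = 0.0,
    polarity: str = "trait",
) -> ParentalTypeTable:
    """Count parental types and compute transmission coefficients.

    Requires a table filtered to networks with at least one parent and
    one friend and with no missing scores.  ``polarity='opposite'``
    returns the complement table directly.
    """
    if table.n_networks == 0:
        raise ValueError("no networks in table")
    ind = _trait_indicators(table, factor, threshold)
    types = ind.apply(
        lambda r: classify_parental_type(int(r["vertical"]), int(r["horizontal"])), axis=1
    )
    P = {t: int((types == t).sum()) for t in PARENTAL_TYPES}
    N = {t: int(ind.loc[types == t, "student"].sum()) for t in PARENTAL_TYPES}
    tab = ParentalTypeTable.from_counts(P, N, factor=factor, polarity="trait")
    for t in PARENTAL_TYPES:
        if P[t] == 0:
            logger.warning("%s: parental type %s empty; B undefined", factor, t)
    return tab if polarity == "trait" else opposite_table(tab)


def opposite_table(t: ParentalTypeTable) -> ParentalTypeTable:
    """Complement table for the opposite trait, on inverse parental types.

    A network of type VH for the trait is of type vh for the opposite
    trait, and a student lacking the trait has its opposite, so
    ``P'_i = P_inv(i)``, ``N'_i = P_inv(i) - N_inv(i)`` and
    ``B'_i = 1 - B_inv(i)``.  Applying it twice returns the original.
    """
    P = {i: int(t.P[_INVERSE[i]]) for i in PARENTAL_TYPES}
    N = {i: int(t.P[_INVERSE[i]] - t.N[_INVERSE[i]]) for i in PARENTAL_TYPES}
    polarity = "opposite" if t.polarity == "trait" else "trait"
    out = ParentalTypeTable.from_counts(P, N, factor=t.factor, polarity=polarity)
    if {"ci_low", "ci_high"} <= set(t.data.columns):
        for i in PARENTAL_TYPES:
            out.data.loc[i, "ci_low"] = 1.0 - t.data.loc[_INVERSE[i], "ci_high"]
            out.data.loc[i, "ci_high"] = 1.0 - t.data.loc[_INVERSE[i], "ci_low"]
    return out


def bootstrap_ci(
    table: NetworkTable,
    factor: str,
    n_boot: int = 10_000,
    seed: int = 0,
    threshold: float = 0.0,
) -> ParentalTypeTable:
    """Percentile bootstrap 95% CIs for the transmission coefficients.

    Networks are resampled with replacement ``n_boot`` times (realised as
    multinomial draws over the eight (type, student-trait) cells, which
    is the same resampling distribution) and ``B_i`` recomputed per
    resample; the CI is the 2.5/97.5 percentile band.  Types empty in the
    original data get an undefined (NaN) CI; resamples in which a type
    comes out empty contribute no value for that type.  Deterministic
    given ``seed``.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    ind = _trait_indicators(table, factor, threshold)
    types = ind.apply(
        lambda r: classify_parental_type(int(r["vertical"]), int(r["horizontal"])), axis=1
    )
    # cell index: 2*type + student_trait
    cells = np.zeros(8, dtype=int)
    for ti, t in enumerate(PARENTAL_TYPES):
        mask = types == t
        s = ind.loc[mask, "student"]
        cells[2 * ti] = int((s == 0).sum())
        cells[2 * ti + 1] = int((s == 1).sum())
    n = cells.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, cells / n, size=n_boot)  # (n_boot, 8)
    tab = transmission_table(table, factor, threshold)
    for ti, t in enumerate(PARENTAL_TYPES):
        Pb = draws[:, 2 * ti] + draws[:, 2 * ti + 1]
        Nb = draws[:, 2 * ti + 1]
        if cells[2 * ti] + cells[2 * ti + 1] == 0:
            tab.data.loc[t, ["ci_low", "ci_high"]] = np.nan
            logger.warning("%s: type %s empty, CI undefined", factor, t)
            continue
        with np.errstate(invalid="ignore"):
            Bb = np.where(Pb > 0, Nb / np.maximum(Pb, 1), np.nan)
        lo, hi = np.nanpercentile(Bb, [2.5, 97.5])
        tab.data.loc[t, "ci_low"] = lo
        tab.data.loc[t, "ci_high"] = hi
    return tab


# -- bias estimation ---------------------------------------------------

@dataclass(frozen=True)
class BiasEstimate:
    """Fitted Vertical/Horizontal/Other biases for one factor.

    Vertical and Horizontal are shared between the trait and its
    opposite; each polarity has its own Other baseline.  All four rates
    are non-negative and each polarity's cell probabilities stay in
    [0, 1] (``other + vertical + horizontal <= 1``).
    """

    vertical: float
    horizontal: float
    other_trait: float
    other_opposite: float
    objective: str
    objective_value: float
    grid_resolution: float

    def to_dict(self) -> dict:
        return {
            "vertical": self.vertical,
            "horizontal": self.horizontal,
            "other_trait": self.other_trait,
            "other_opposite": self.other_opposite,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "grid_resolution": self.grid_resolution,
        }


def _cell_objective(
    N: np.ndarray, P: np.ndarray, p: np.ndarray, objective: str
) -> np.ndarray:
    """Objective contribution of the four cells; ``p`` has shape (..., 4)."""
    mask = P > 0
    if objective == "binomial_loglik":
        # negative log-likelihood; impossible cells (p=0 with N>0 etc.) -> inf
        from scipy.special import xlogy

        with np.errstate(divide="ignore", invalid="ignore"):
            ll = xlogy(N, p) + xlogy(P - N, 1.0 - p)
        ll = np.where(mask, ll, 0.0)
        out = -np.sum(ll, axis=-1)
        return np.where(np.isnan(out), np.inf, out)
    if objective == "sse_proportions":
        B = np.where(mask, N / np.maximum(P, 1), 0.0)
        d = np.where(mask, B - p, 0.0)
        return np.sum(d * d, axis=-1)
    if objective == "sse_counts":
        d = np.where(mask, N - P * p, 0.0)
        return np.sum(d * d, axis=-1)
    raise ValueError(f"unknown objective {objective!r}; choose one of {OBJECTIVES}")


def _design() -> np.ndarray:
    # rows = types in PARENTAL_TYPES order, cols = (other, vertical, horizontal)
    return np.array([[1, v, h] for (v, h) in (_TYPE_VH[t] for t in PARENTAL_TYPES)],
                    dtype=float)


def estimate_biases(
    trait_table: ParentalTypeTable,
    opp_table: ParentalTypeTable | None = None,
    objective: str = "binomial_loglik",
    grid_resolution: float = 0.01,
) -> BiasEstimate:
    """Exhaustive grid search for the additive transmission biases.

    The four trait cells are modelled as ``N_i ~ Binomial(P_i, p_i)``
    with ``p_i = other_trait + vertical*v_i + horizontal*h_i`` and the
    opposite-trait cells likewise with ``other_opposite``; Vertical and
    Horizontal are shared.  Every grid point on the constrained simplex
    (all rates >= 0, ``other + vertical + horizontal <= 1`` per polarity)
    is scanned; for fixed (vertical, horizontal) the two Other scans
    decouple, which makes the exhaustive search cheap.  Ties are broken
    by the lexicographically smallest (vertical, horizontal, other_trait,
    other_opposite), so results are platform-reproducible.

    ``objective`` is one of ``binomial_loglik`` (negative binomial
    log-likelihood, the default), ``sse_proportions`` (squared error on
    the B_i) or ``sse_counts`` (squared error on the N_i).
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; choose one of {OBJECTIVES}")
    g = float(grid_resolution)
    if not 0 < g <= 0.5:
        raise ValueError(f"grid_resolution must be in (0, 0.5], got {g}")
    if opp_table is None:
        opp_table = opposite_table(trait_table)
    if trait_table.polarity == opp_table.polarity:
        raise ValueError("tables must have opposite polarities")
    if trait_table.polarity == "opposite":
        trait_table, opp_table = opp_table, trait_table

    Nt = trait_table.N.to_numpy(float)
    Pt = trait_table.P.to_numpy(float)
    No = opp_table.N.to_numpy(float)
    Po = opp_table.P.to_numpy(float)
    if Pt.sum() == 0:
        raise ValueError("no networks counted; empty feasible grid")

    X = _design()  # (4, 3)
    eps = 1e-9
    m = int(round(1.0 / g))
    grid = np.round(np.arange(m + 1) * g, 12)
    grid = grid[grid <= 1.0 + eps]

    best = (np.inf, None)  # (objective value, (v, h, ot, oo))
    for v in grid:  # ascending: first strict improvement wins => lexicographic
        h_max = 1.0 - v + eps
        H = grid[grid <= h_max]
        if H.size == 0:
            continue
        # other grid: for each h, feasible ot/oo <= 1 - v - h
        OT = grid  # (T,)
        feas = OT[None, :] <= (1.0 - v - H[:, None]) + eps  # (Hn, T)
        if not feas.any():
            continue
        # cell probabilities p = ot + v*vi + h*hi : shape (Hn, T, 4)
        base = v * X[:, 1]  # (4,)
        p = (
            OT[None, :, None]
            + base[None, None, :]
            + H[:, None, None] * X[None, None, :, 2].reshape(1, 1, 4)
        )
        p = np.clip(p, 0.0, 1.0)
        obj_t = _cell_objective(Nt, Pt, p, objective)  # (Hn, T)
        obj_o = _cell_objective(No, Po, p, objective)  # (Hn, T)
        big = np.inf
        obj_t = np.where(feas, obj_t, big)
        obj_o = np.where(feas, obj_o, big)
        it = np.argmin(obj_t, axis=1)  # first occurrence: smallest ot
        io = np.argmin(obj_o, axis=1)
        tot = obj_t[np.arange(len(H)), it] + obj_o[np.arange(len(H)), io]
        ih = int(np.argmin(tot))  # first occurrence: smallest h
        if tot[ih] < best[0]:
            best = (float(tot[ih]), (float(v), float(H[ih]),
                                     float(OT[it[ih]]), float(OT[io[ih]])))
    if best[1] is None:
        raise ValueError("empty feasible grid")
    v, h, ot, oo = best[1]
    return BiasEstimate(
        vertical=v,
        horizontal=h,
        other_trait=ot,
        other_opposite=oo,
        objective=objective,
        objective_value=best[0],
        grid_resolution=g,
    )


# -- triangle (barycentric) coordinates --------------------------------

#: corners of the bias triangle: Vertical top, Horizontal bottom-left,
#: Other bottom-right
_TRIANGLE_CORNERS = {
    "vertical": (0.5, np.sqrt(3.0) / 2.0),
    "horizontal": (0.0, 0.0),
    "other": (1.0, 0.0),
}


def triangle_coordinates(estimate: BiasEstimate) -> dict[str, dict[str, float]]:
    """Normalised bias weights and 2-D triangle-plot coordinates.

    For each polarity the (vertical, horizontal, other) biases are
    normalised to sum to 1 and placed barycentrically in the triangle;
    proximity to a corner means that bias dominates.  A polarity whose
    three biases are all zero sits at the centroid.
    """
    out = {}
    for polarity, other in (
        ("trait", estimate.other_trait),
        ("opposite", estimate.other_opposite),
    ):
        w = np.array([estimate.vertical, estimate.horizontal, other], dtype=float)
        total = w.sum()
        w = w / total if total > 0 else np.full(3, 1.0 / 3.0)
        corners = np.array([
            _TRIANGLE_CORNERS["vertical"],
            _TRIANGLE_CORNERS["horizontal"],
            _TRIANGLE_CORNERS["other"],
        ])
        xy = w @ corners
        out[polarity] = {
            "vertical": float(w[0]),
            "horizontal": float(w[1]),
            "other": float(w[2]),
            "x": float(xy[0]),
            "y": float(xy[1]),
        }
    return out
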