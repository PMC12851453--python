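"""Core data structures and plumbing for family-and-friend network tables.

The central object is the :class:`NetworkTable`: a long-format table of
factor scores, one row per ``(network_id, role, factor)``.  A *network* is
one student plus any of their recruited parents, grandparents and friends.
Everything downstream (resemblance statistics, transmission coefficients,
bias estimation) consumes this table.

Scores are latent factor scores (e.g. Religiosity, Politics) centred so
that 0 is the factor mean; dichotomising at 0 therefore splits the
population into trait / opposite-trait halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "PARENT_ROLES",
    "FRIEND_ROLES",
    "GRANDPARENT_ROLES",
    "DEFAULT_FACTORS",
    "NetworkTable",
    "TraitValue",
    "FilterReport",
    "read_network_table",
    "write_network_table",
    "filter_networks",
    "aggregate_components",
    "dichotomize",
    "dichotomize_scores",
    "impute_missing",
    "IMPUTERS",
]


class Role(str, Enum):
    """The ten social-agent roles a network may contain.

    ``student`` is the focal agent (time 1) and is required in every
    network; ``student_t2`` is the same student's retest a few weeks
    later, used only for reliability.
    """

    STUDENT = "student"
    STUDENT_T2 = "student_t2"
    FRIEND1 = "friend1"
    FRIEND2 = "friend2"
    MOTHER = "mother"
    FATHER = "father"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"
    MATERNAL_GRANDFATHER = "maternal_grandfather"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    PATERNAL_GRANDFATHER = "paternal_grandfather"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PARENT_ROLES = frozenset({Role.MOTHER, Role.FATHER})
FRIEND_ROLES = frozenset({Role.FRIEND1, Role.FRIEND2})
GRANDPARENT_ROLES = frozenset(
    {
        Role.MATERNAL_GRANDMOTHER,
        Role.MATERNAL_GRANDFATHER,
        Role.PATERNAL_GRANDMOTHER,
        Role.PATERNAL_GRANDFATHER,
    }
)

#: The eight attitude/behaviour factors, in canonical order.
DEFAULT_FACTORS: tuple[str, ...] = (
    "Religiosity",
    "Politics",
    "Environmentalism",
    "Health",
    "Music",
    "Reading",
    "Screen",
    "Social",
)

_COLUMNS = ["network_id", "role", "factor", "score"]


@dataclass(frozen=True)
class TraitValue:
    """A dichotomised trait indicator with its polarity.

    ``value`` is 1 when the agent has the trait under the given polarity.
    The opposite polarity is always the complement.
    """

    value: int
    polarity: str = "trait"

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"trait value must be 0 or 1, got {self.value}")
        if self.polarity not in ("trait", "opposite"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def opposite(self) -> "TraitValue":
        pol = "opposite" if self.polarity == "trait" else "trait"
        return TraitValue(1 - self.value, pol)


@dataclass
class NetworkTable:
    """Long-format container of per-agent factor scores.

    Parameters
    ----------
    df
        DataFrame with columns ``network_id, role, factor, score``.
        ``score`` may contain NaN before imputation.
    factor_labels
        Ordered factor labels; defaults to the factors present in ``df``
        (in :data:`DEFAULT_FACTORS` order where applicable).
    """

    df: pd.DataFrame
    factor_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in _COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        df = df[_COLUMNS].copy()
        df["network_id"] = df["network_id"].astype(str)
        df["role"] = df["role"].map(lambda r: Role(r).value)
        df["factor"] = df["factor"].astype(str)
        df["score"] = pd.to_numeric(df["score"], errors="raise").astype(float)

        dup = df.duplicated(subset=["network_id", "role", "factor"], keep=False)
        if dup.any():
            key = df.loc[dup, ["network_id", "role", "factor"]].iloc[0]
            raise ValueError(
                "duplicate record for key "
                f"({key.network_id!r}, {key.role!r}, {key.factor!r})"
            )
        roles_by_net = df.groupby("network_id")["role"].unique()
        without_student = [
            nid for nid, roles in roles_by_net.items() if Role.STUDENT.value not in roles
        ]
        if without_student:
            raise ValueError(
                f"networks missing the student role: {sorted(without_student)[:5]}"
            )
        if np.isinf(df["score"].to_numpy()).any():
            raise ValueError("scores must be finite or missing (NaN)")

        object.__setattr__(self, "df", df.reset_index(drop=True))
        if not self.factor_labels:
            present = pd.unique(df["factor"])
            ordered = [f for f in DEFAULT_FACTORS if f in set(present)]
            ordered += [f for f in present if f not in set(ordered)]
            object.__setattr__(self, "factor_labels", tuple(ordered))

    # -- basic queries -------------------------------------------------

    @property
    def network_ids(self) -> list[str]:
        return sorted(self.df["network_id"].unique())

    @property
    def n_networks(self) -> int:
        return self.df["network_id"].nunique()

    def roles_in_network(self, network_id: str) -> set[Role]:
        sub = self.df.loc[self.df["network_id"] == str(network_id), "role"]
        return {Role(r) for r in sub.unique()}

    def wide(self, factor: str) -> pd.DataFrame:
        """Networks x roles matrix of scores for one factor (NaN = absent)."""
        sub = self.df[self.df["factor"] == factor]
        return sub.pivot(index="network_id", columns="role", values="score")

    def n_missing(self) -> int:
        return int(self.df["score"].isna().sum())

    # -- IO ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        write_network_table(self, path)


def read_network_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> NetworkTable:
    """Read a long-format CSV of factor scores into a :class:`NetworkTable`.

    Rows whose role is not one of the ten known roles (e.g. other
    relatives such as aunts) are dropped with a logged count, mirroring
    how surveyed "other relatives" are excluded from analysis.  A missing
    score is an empty field.

    Parameters
    ----------
    schema
        Optional mapping from the canonical column names
        (``network_id, role, factor, score``) to the column names used in
        the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in _COLUMNS}
    if schema:
        colmap.update(schema)
    missing_cols = [v for v in colmap.values() if v not in raw.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path.name}: {missing_cols}")
    df = pd.DataFrame({k: raw[v] for k, v in colmap.items()})

    # validate scores row-by-row so we can report file line numbers
    scores = pd.to_numeric(df["score"].replace("", np.nan), errors="coerce")
    bad = df["score"].ne("") & scores.isna()
    if bad.any():
        lines = (bad[bad].index + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed score values at lines {lines[:10]}")
    df["score"] = scores

    known = {r.value for r in Role}
    unknown = ~df["role"].isin(known)
    if unknown.any():
        dropped = df.loc[unknown, "role"].value_counts().to_dict()
        logger.warning(
            "dropped %d rows with unknown roles (not used in analysis): %s",
            int(unknown.sum()),
            dropped,
        )
        df = df[~unknown]
    return NetworkTable(df.reset_index(drop=True))


def write_network_table(table: NetworkTable, path: str | Path) -> None:
    """Write a :class:`NetworkTable` to CSV (empty field = missing score)."""
    out = table.df.copy()
    out = out.sort_values(["network_id", "role", "factor"], kind="mergesort")
    out.to_csv(path, index=False, float_format="%.17g")


# -- filtering ---------------------------------------------------------

_FILTER_RULES = ("student_plus_any", "parent_and_friend", "parent_friend_and_grandparent")


@dataclass
class FilterReport:
    rule: str
    n_in: int
    n_retained: int
    n_excluded: int


def _network_satisfies(roles: set[Role], rule: str) -> bool:
    has_parent = bool(roles & PARENT_ROLES)
    has_friend = bool(roles & FRIEND_ROLES)
    has_grandparent = bool(roles & GRANDPARENT_ROLES)
    others = roles - {Role.STUDENT, Role.STUDENT_T2}
    if rule == "student_plus_any":
        return bool(others)
    if rule == "parent_and_friend":
        return has_parent and has_friend
    if rule == "parent_friend_and_grandparent":
        return has_parent and has_friend and has_grandparent
    raise ValueError(f"unknown filter rule {rule!r}; choose one of {_FILTER_RULES}")


def filter_networks(
    table: NetworkTable,
    rule: str,
    *,
    with_report: bool = False,
) -> NetworkTable | tuple[NetworkTable, FilterReport]:
    """Retain networks whose composition satisfies an inclusion rule.

    Rules
    -----
    ``student_plus_any``
        at least one family member or friend besides the student (the
        survey's basic inclusion: student-only networks are excluded)
    ``parent_and_friend``
        at least one parent and at least one friend (required for the
        additive transmission model)
    ``parent_friend_and_grandparent``
        additionally at least one grandparent
    """
    if rule not in _FILTER_RULES:
        raise ValueError(f"unknown filter rule {rule!r}; choose one of {_FILTER_RULES}")
    df = table.df
    roles_by_net = df.groupby("network_id")["role"].agg(lambda s: {Role(r) for r in s})
    keep_ids = {nid for nid, roles in roles_by_net.items() if _network_satisfies(roles, rule)}
    out_df = df[df["network_id"].isin(keep_ids)].reset_index(drop=True)
    report = FilterReport(
        rule=rule,
        n_in=int(roles_by_net.shape[0]),
        n_retained=len(keep_ids),
        n_excluded=int(roles_by_net.shape[0]) - len(keep_ids),
    )
    logger.info(
        "filter %s: retained %d of %d networks (%d excluded)",
        rule, report.n_retained, report.n_in, report.n_excluded,
    )
    if out_df.empty:
        out = NetworkTable(
            pd.DataFrame(columns=_COLUMNS), factor_labels=table.factor_labels
        )
    else:
        out = NetworkTable(out_df, factor_labels=table.factor_labels)
    return (out, report) if with_report else out


# -- relationship aggregation -----------------------------------------

_COMPONENT_ROLES: dict[str, frozenset[Role]] = {
    "vertical": PARENT_ROLES,
    "horizontal": FRIEND_ROLES,
    "grandparental": GRANDPARENT_ROLES,
}


def aggregate_components(table: NetworkTable) -> pd.DataFrame:
    """Average scores within each relationship into network components.

    Per network and factor the mother/father scores are averaged into a
    *vertical* component, the two friends into a *horizontal* component
    and the grandparents into a *grandparental* component; when only one
    member of a relationship is present, that member's score passes
    through; when none is present the component is NaN (absent — absence
    is a value, not zero).  The student-retest scores never enter any
    component.

    Returns a DataFrame indexed by ``(network_id, factor)`` with columns
    ``student, vertical, horizontal, grandparental``.
    """
    df = table.df
    wide = df.pivot(index=["network_id", "factor"], columns="role", values="score")
    out = pd.DataFrame(index=wide.index)
    out["student"] = wide.get(Role.STUDENT.value)
    for name, roles in _COMPONENT_ROLES.items():
        cols = [r.value for r in sorted(roles, key=lambda r: r.value) if r.value in wide.columns]
        if cols:
            out[name] = wide[cols].mean(axis=1)  # mean over available members
        else:
            out[name] = np.nan
    return out


# -- dichotomisation ---------------------------------------------------

def dichotomize(score: float, threshold: float = 0.0) -> TraitValue:
    """Convert a score to a binary trait: ``score >= threshold`` has it.

    The default threshold of 0 is the factor-score mean, so an exactly
    average individual counts as having the trait.
    """
    if not np.isfinite(score):
        raise ValueError(f"cannot dichotomize non-finite score {score!r}")
    return TraitValue(int(score >= threshold), "trait")


def dichotomize_scores(scores: np.ndarray | pd.Series, threshold: float = 0.0):
    """Vectorised ``dichotomize``; NaN propagates (absent stays absent)."""
    arr = np.asarray(scores, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("cannot dichotomize infinite scores")
    out = np.where(arr >= threshold, 1.0, 0.0)
    out = np.where(np.isnan(arr), np.nan, out)
    if isinstance(scores, pd.Series):
        return pd.Series(out, index=scores.index, name=scores.name)
    return out


# -- imputation --------------------------------------------------------

def _impute_column_mean(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    out = df.copy()
    means = out.groupby("factor")["score"].transform("mean")
    out["score"] = out["score"].fillna(means)
    return out


#: Registry of pluggable imputers: name -> callable(df, rng) -> df.
IMPUTERS: dict[str, Callable[[pd.DataFrame, np.random.Generator], pd.DataFrame]] = {
    "column_mean": _impute_column_mean,
}


def impute_missing(
    table: NetworkTable,
    method: str = "column_mean",
    seed: int = 0,
) -> NetworkTable:
    """Fill missing scores with a pluggable imputer (default: factor mean).

    Deterministic given ``seed`` (the default imputer is deterministic
    outright; the seed is threaded through so stochastic imputers plug in
    without interface change).  Missingness above 50% in any factor, or a
    fully missing factor, is refused.
    """
    if method not in IMPUTERS:
        raise ValueError(f"unknown imputer {method!r}; available: {sorted(IMPUTERS)}")
    df = table.df
    frac = df.groupby("factor")["score"].agg(lambda s: s.isna().mean())
    all_missing = frac[frac >= 1.0]
    if not all_missing.empty:
        raise ValueError(f"factor(s) entirely missing: {list(all_missing.index)}")
    too_missing = frac[frac >= 0.5]
    if not too_missing.empty:
        raise ValueError(
            f"factor(s) with >=50% missing scores: {list(too_missing.index)}"
        )
    n_before = int(df["score"].isna().sum())
    if n_before == 0:
        return NetworkTable(df.copy(), factor_labels=table.factor_labels)
    rng = np.random.default_rng(seed)
    out = IMPUTERS[method](df, rng)
    logger.info("imputed %d missing scores with %s", n_before, method)
    if out["score"].isna().any():
        raise RuntimeError(f"imputer {method!r} left missing scores")
    return NetworkTable(out, factor_labels=table.factor_labels)
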