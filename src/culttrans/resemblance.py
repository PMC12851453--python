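"""Resemblance: Monte-Carlo permutation z-scores for dyadic correlations.

For a pair of roles (say students and mothers) and one factor, the
*veridical* Pearson correlation is computed over networks in which both
roles are present.  A null distribution is built by scrambling the
pairing — correlating each student with a random mother from the sample
— many times; the z-score of the veridical correlation within that null
is the **Resemblance**.  It is the cultural analogue of broad
heritability: how much more a student resembles *their* mother than a
random mother from the population.  If everyone is alike, correlations
are high across the board but Resemblance is low.

Significance tiers follow the conventional normal cuts: z > 3.3
("strong", p < 0.001) and z > 1.96 ("weak", p < 0.05).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    FRIEND_ROLES,
    GRANDPARENT_ROLES,
    PARENT_ROLES,
    NetworkTable,
    Role,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResemblanceResult",
    "ResemblanceGraph",
    "pearson_pair",
    "resemblance_z",
    "resemblance_graph",
    "vertical_horizontal_summary",
    "edge_category",
    "tier_for_z",
    "DEFAULT_N_PERM",
    "Z_WEAK",
    "Z_STRONG",
]

DEFAULT_N_PERM = 10_000
Z_WEAK = 1.96
Z_STRONG = 3.3

_COUPLES = (
    frozenset({Role.MOTHER, Role.FATHER}),
    frozenset({Role.MATERNAL_GRANDMOTHER, Role.MATERNAL_GRANDFATHER}),
    frozenset({Role.PATERNAL_GRANDMOTHER, Role.PATERNAL_GRANDFATHER}),
)


@dataclass(frozen=True)
class ResemblanceResult:
    """Veridical correlation and its permutation z-score for one role pair."""

    role_pair: tuple[str, str]
    factor: str
    r_veridical: float
    z: float
    n_pairs: int
    n_perm: int
    p_mc: float
    p_parametric: float

    def to_dict(self) -> dict:
        return {
            "role_pair": list(self.role_pair),
            "factor": self.factor,
            "r_veridical": self.r_veridical,
            "z": self.z,
            "n_pairs": self.n_pairs,
            "n_perm": self.n_perm,
            "p_mc": self.p_mc,
            "p_parametric": self.p_parametric,
        }


def pearson_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two paired score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("scores must be finite (impute or drop missing first)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(x, y).statistic)


def _aligned_pair(
    table: NetworkTable, pair: tuple[Role | str, Role | str], factor: str
) -> tuple[np.ndarray, np.ndarray]:
    a, b = Role(pair[0]).value, Role(pair[1]).value
    if a == b:
        raise ValueError("role pair must contain two distinct roles")
    wide = table.wide(factor)
    for r in (a, b):
        if r not in wide.columns:
            raise ValueError(f"role {r!r} absent from all networks for {factor!r}")
    sub = wide[[a, b]].dropna()
    return sub[a].to_numpy(), sub[b].to_numpy()


def resemblance_z(
    table: NetworkTable,
    pair: tuple[Role | str, Role | str],
    factor: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> ResemblanceResult:
    """Resemblance z-score for one role pair and factor.

    The pairing of the second role's scores with the first role's is
    scrambled uniformly at random across networks ``n_perm`` times
    (marginals preserved); ``z = (r - mean(null)) / sd(null)``.  Only the
    second vector is permuted — permuting both is redundant under
    exchangeability.  Networks missing either role are dropped pairwise.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    x, y = _aligned_pair(table, pair, factor)
    n = len(x)
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs for {pair} / {factor}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero variance for {pair} / {factor}")
    r = pearson_pair(x, y)
    p_param = float(stats.pearsonr(x, y).pvalue)

    rng = np.random.default_rng(seed)
    u = (x - x.mean()) / x.std(ddof=1)
    v = (y - y.mean()) / y.std(ddof=1)
    null = np.empty(n_perm)
    chunk = max(1, int(5_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)  # m uniform permutations
        null[done : done + m] = v[idx] @ u / (n - 1)
        done += m
    mu, sd = null.mean(), null.std(ddof=1)
    z = float((r - mu) / sd)
    p_mc = float((np.count_nonzero(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
    return ResemblanceResult(
        role_pair=(Role(pair[0]).value, Role(pair[1]).value),
        factor=factor,
        r_veridical=r,
        z=z,
        n_pairs=n,
        n_perm=n_perm,
        p_mc=p_mc,
        p_parametric=p_param,
    )


def tier_for_z(z: float) -> str:
    """Significance tier: ``strong`` (z > 3.3), ``weak`` (z > 1.96) or ``none``."""
    if z > Z_STRONG:
        return "strong"
    if z > Z_WEAK:
        return "weak"
    return "none"


def edge_category(pair: tuple[Role | str, Role | str]) -> str:
    """Transmission-pathway category of a role pair.

    parent-student and grandparent-parent links are *direct vertical*;
    grandparent-student links are *indirect vertical*; friend-student
    links and the three couples are *horizontal*; everything else
    (including the student retest) is *other*.
    """
    a, b = Role(pair[0]), Role(pair[1])
    s = {a, b}
    if s in _COUPLES:
        return "horizontal"
    if Role.STUDENT in s:
        other = (s - {Role.STUDENT}).pop()
        if other in PARENT_ROLES:
            return "direct_vertical"
        if other in FRIEND_ROLES:
            return "horizontal"
        if other in GRANDPARENT_ROLES:
            return "indirect_vertical"
        return "other"
    if (s & PARENT_ROLES) and (s & GRANDPARENT_ROLES):
        return "direct_vertical"
    return "other"


@dataclass
class ResemblanceGraph:
    """Edge list of Resemblance values over all role pairs and factors."""

    edges: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "edges": self.edges,
            "skipped": self.skipped,
        }

    def edge(self, pair: tuple[str, str], factor: str) -> dict | None:
        key = tuple(sorted(Role(r).value for r in pair))
        for e in self.edges:
            if tuple(sorted(e["role_pair"])) == key and e["factor"] == factor:
                return e
        return None


def _graph_pairs() -> list[tuple[str, str]]:
    # all unordered role pairs; the student retest enters only via the
    # student/student_t2 reliability pair
    roles = [r for r in Role if r is not Role.STUDENT_T2]
    pairs = [
        (a.value, b.value) for a, b in itertools.combinations(roles, 2)
    ]
    pairs.append((Role.STUDENT.value, Role.STUDENT_T2.value))
    return sorted(tuple(sorted(p)) for p in pairs)


def resemblance_graph(
    table: NetworkTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> ResemblanceGraph:
    """Resemblance for every role pair and factor, tiered and categorised.

    Pairs that cannot be tested (role absent everywhere, fewer than 3
    complete pairs, zero variance) are recorded under ``skipped`` with
    the reason.  Each (pair, factor) cell gets an independent child
    stream of ``seed``, so the graph is reproducible and insensitive to
    evaluation order.
    """
    graph = ResemblanceGraph(n_perm=n_perm, seed=seed)
    pairs = _graph_pairs()
    for pi, pair in enumerate(pairs):
        for fi, factor in enumerate(table.factor_labels):
            rng = np.random.default_rng([seed, pi, fi])
            try:
                res = resemblance_z(table, pair, factor, n_perm=n_perm, seed=rng)
            except ValueError as exc:
                graph.skipped.append(
                    {"role_pair": list(pair), "factor": factor, "reason": str(exc)}
                )
                continue
            graph.edges.append(
                {
                    **res.to_dict(),
                    "tier": tier_for_z(res.z),
                    "category": edge_category(pair),
                }
            )
    logger.info(
        "resemblance graph: %d edges, %d skipped", len(graph.edges), len(graph.skipped)
    )
    return graph


def vertical_horizontal_summary(table: NetworkTable) -> pd.DataFrame:
    """Per-factor averaged vertical and horizontal correlations.

    Vertical = mean of the mother-student and father-student Pearson
    correlations; horizontal = mean of the friend1-student and
    friend2-student correlations; each constituent computed over the
    networks where both members are present, and skipped (with a log
    line) when undefined.
    """
    records = []
    for factor in table.factor_labels:
        wide = table.wide(factor)
        row: dict[str, float | str | int] = {"factor": factor}
        for name, roles in (("vertical", PARENT_ROLES), ("horizontal", FRIEND_ROLES)):
            rs, ns = [], []
            for role in sorted(r.value for r in roles):
                if role not in wide.columns:
                    logger.info("%s/%s: role %s absent, skipped", factor, name, role)
                    continue
                sub = wide[[Role.STUDENT.value, role]].dropna()
                if len(sub) < 3 or sub.iloc[:, 0].nunique() < 2 or sub.iloc[:, 1].nunique() < 2:
                    logger.info("%s/%s: %s-student correlation undefined, skipped",
                                factor, name, role)
                    continue
                rs.append(pearson_pair(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()))
                ns.append(len(sub))
            row[f"{name}_r"] = float(np.mean(rs)) if rs else np.nan
            row[f"{name}_n_pairs"] = int(np.sum(ns)) if ns else 0
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("factor")
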