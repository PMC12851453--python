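"""Synthetic family-and-friend network populations.

Two generators produce :class:`~culttrans.data_model.NetworkTable`
populations with known ground truth, so every downstream stage
(resemblance, transmission coefficients, bias estimation) can be tested
end-to-end without survey data:

``generate_binary_population``
    draws binary cultural traits per network under the additive
    transmission model: the probability a student adopts a trait is
    ``other + vertical * v + horizontal * h`` where ``v``/``h`` are the
    trait indicators of the parental (Vertical) and friend (Horizontal)
    components.  Traits are emitted as signed scores (+1 has the trait,
    -1 does not) so the standard dichotomise-at-zero rule recovers them,
    with a tied couple (one member each way) counting as having the
    trait, matching the >= 0 convention.

``generate_continuous_population``
    draws correlated continuous factor scores via a Gaussian copula whose
    pairwise role-role correlations hit configurable targets, with
    configurable network composition and missing-completely-at-random
    holes — the statistical structure the resemblance analysis assumes.

Randomness is hierarchical: each network gets its own independent stream
keyed by ``(seed, stream_tag, network_index)``, so a population is
reproducible and can be extended without reshuffling earlier networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_FACTORS,
    FRIEND_ROLES,
    GRANDPARENT_ROLES,
    PARENT_ROLES,
    NetworkTable,
    Role,
)

__all__ = [
    "Biases",
    "GeneratorConfig",
    "GroundTruth",
    "generate_binary_population",
    "generate_continuous_population",
    "DEFAULT_CORR_TARGETS",
]


@dataclass(frozen=True)
class Biases:
    """Additive transmission biases for one factor.

    ``vertical`` and ``horizontal`` are the probability increments of a
    student adopting the trait when the parental / friend component has
    it; ``other_trait`` is the baseline adoption rate from sources
    outside the network (media, teachers, invention).  ``other_opposite``
    is determined by complementarity
    (``1 - other_trait - vertical - horizontal``) because a student who
    does not adopt the trait has its opposite; it may be supplied for
    validation but cannot be set freely.
    """

    vertical: float = 0.0
    horizontal: float = 0.0
    other_trait: float = 0.5
    other_opposite: float | None = None

    def __post_init__(self) -> None:
        for name in ("vertical", "horizontal", "other_trait"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"bias {name}={v} outside [0, 1]")
        total = self.other_trait + self.vertical + self.horizontal
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"other_trait + vertical + horizontal = {total:.4f} exceeds 1"
            )
        derived = 1.0 - total
        if self.other_opposite is None:
            object.__setattr__(self, "other_opposite", derived)
        elif abs(self.other_opposite - derived) > 1e-9:
            raise ValueError(
                f"other_opposite={self.other_opposite} inconsistent with "
                f"complementarity (must equal {derived:.6f})"
            )


def _default_role_presence() -> dict[str, float]:
    # everyone needed by the additive model present; reliability/grandparent
    # roles off by default
    p = {r.value: 0.0 for r in Role}
    for r in (Role.STUDENT, Role.MOTHER, Role.FATHER, Role.FRIEND1, Role.FRIEND2):
        p[r.value] = 1.0
    return p


def _survey_role_presence() -> dict[str, float]:
    # loosely calibrated to the survey's per-role participation rates
    # (mothers in ~44% of networks, fathers ~37%, ~1 friend per student,
    # grandparents sparse); the joint composition distribution is not
    # fitted to anything.
    return {
        Role.STUDENT.value: 1.0,
        Role.STUDENT_T2.value: 0.5,
        Role.FRIEND1.value: 0.48,
        Role.FRIEND2.value: 0.48,
        Role.MOTHER.value: 0.44,
        Role.FATHER.value: 0.37,
        Role.MATERNAL_GRANDMOTHER.value: 0.14,
        Role.MATERNAL_GRANDFATHER.value: 0.08,
        Role.PATERNAL_GRANDMOTHER.value: 0.07,
        Role.PATERNAL_GRANDFATHER.value: 0.05,
    }


def _pair_key(a: Role | str, b: Role | str) -> tuple[str, str]:
    a, b = Role(a).value, Role(b).value
    return (a, b) if a <= b else (b, a)


#: Default role-pair correlation targets for the continuous generator,
#: echoing the magnitudes of the survey's pairwise correlation structure:
#: strong retest reliability, strong within-couple similarity, moderate
#: parent-student and friend-student similarity, weak background
#: clustering between unconnected agents.
DEFAULT_CORR_TARGETS: dict[tuple[str, str], float] = {
    _pair_key(Role.STUDENT, Role.STUDENT_T2): 0.85,
    _pair_key(Role.STUDENT, Role.MOTHER): 0.35,
    _pair_key(Role.STUDENT, Role.FATHER): 0.30,
    _pair_key(Role.STUDENT, Role.FRIEND1): 0.30,
    _pair_key(Role.STUDENT, Role.FRIEND2): 0.30,
    _pair_key(Role.MOTHER, Role.FATHER): 0.55,
    _pair_key(Role.MATERNAL_GRANDMOTHER, Role.MATERNAL_GRANDFATHER): 0.60,
    _pair_key(Role.PATERNAL_GRANDMOTHER, Role.PATERNAL_GRANDFATHER): 0.60,
    _pair_key(Role.MOTHER, Role.MATERNAL_GRANDMOTHER): 0.35,
    _pair_key(Role.MOTHER, Role.MATERNAL_GRANDFATHER): 0.30,
    _pair_key(Role.FATHER, Role.PATERNAL_GRANDMOTHER): 0.35,
    _pair_key(Role.FATHER, Role.PATERNAL_GRANDFATHER): 0.30,
    _pair_key(Role.FRIEND1, Role.FRIEND2): 0.25,
}

_ROLE_ORDER = [r.value for r in Role]


@dataclass
class GeneratorConfig:
    """Configuration for synthetic network populations.

    Parameters
    ----------
    n_networks
        Number of networks (students) to generate.
    role_presence
        Probability each role is present; the student is always present.
    biases
        Per-factor additive transmission biases (binary generator).
    trait_prev_vertical, trait_prev_horizontal
        Marginal prevalence of the trait in the Vertical / Horizontal
        components (binary generator).
    parent_friend_corr
        Probability the Horizontal component copies the Vertical
        component's trait (else drawn independently); with equal
        prevalences this equals the v-h trait correlation and models a
        clustered social network.
    couple_concordance, friend_concordance
        Probability the second member of a couple / friend pair copies
        the first (else drawn independently at the component prevalence).
    corr_targets
        Role-pair Pearson correlation targets (continuous generator);
        unspecified pairs get ``baseline_corr``.
    missing_rate
        Fraction of scores blanked completely at random, in [0, 0.5).
    """

    n_networks: int = 100
    role_presence: dict[str, float] = field(default_factory=_default_role_presence)
    biases: dict[str, Biases] = field(
        default_factory=lambda: {"Religiosity": Biases(0.42, 0.18, 0.10)}
    )
    trait_prev_vertical: float = 0.5
    trait_prev_horizontal: float = 0.5
    parent_friend_corr: float = 0.0
    couple_concordance: float = 1.0
    friend_concordance: float = 1.0
    corr_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORR_TARGETS)
    )
    baseline_corr: float = 0.10
    factors: tuple[str, ...] = DEFAULT_FACTORS
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_networks <= 0:
            raise ValueError("n_networks must be positive")
        given = {Role(k).value: float(v) for k, v in self.role_presence.items()}
        presence = {r.value: 0.0 for r in Role}
        presence.update(given)
        if Role.STUDENT.value not in given:
            presence[Role.STUDENT.value] = 1.0
        self.role_presence = presence
        for role, p in self.role_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"role_presence[{role!r}]={p} outside [0, 1]")
        if self.role_presence[Role.STUDENT.value] != 1.0:
            raise ValueError("the student must be present in every network")
        for f, b in self.biases.items():
            if not isinstance(b, Biases):
                self.biases[f] = Biases(**b) if isinstance(b, Mapping) else Biases(*b)
        for name in ("trait_prev_vertical", "trait_prev_horizontal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("parent_friend_corr", "couple_concordance", "friend_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.parent_friend_corr > 0 and (
            abs(self.trait_prev_vertical - self.trait_prev_horizontal) > 1e-12
        ):
            raise ValueError(
                "parent_friend_corr > 0 requires equal vertical and horizontal "
                "trait prevalences (the copy construction preserves marginals "
                "only then)"
            )
        self.corr_targets = {_pair_key(*k): float(v) for k, v in self.corr_targets.items()}
        for pair, r in self.corr_targets.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"corr_target{pair}={r} outside [-1, 1]")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError(f"missing_rate={self.missing_rate} outside [0, 0.5)")
        self.factors = tuple(self.factors)

    # -- presets -------------------------------------------------------

    @classmethod
    def recovery_preset(
        cls,
        n_networks: int,
        biases: Mapping[str, Biases] | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "GeneratorConfig":
        """Clean parameter-recovery conditions: student, both parents and
        both friends always present, perfect within-relationship
        concordance, no missingness."""
        b = dict(biases) if biases is not None else {"Religiosity": Biases(0.42, 0.18, 0.10)}
        cfg = cls(
            n_networks=n_networks,
            biases=b,
            factors=tuple(b.keys()),
            seed=seed,
            **kwargs,
        )
        return cfg

    @classmethod
    def survey_preset(cls, n_networks: int, seed: int = 0, **kwargs) -> "GeneratorConfig":
        """Survey-like composition: ragged networks with sparse
        grandparents, a retest for half the students and 2% missing
        responses."""
        kwargs.setdefault("role_presence", _survey_role_presence())
        kwargs.setdefault("missing_rate", 0.02)
        return cls(n_networks=n_networks, seed=seed, **kwargs)

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corr_targets"] = {f"{a}|{b}": v for (a, b), v in self.corr_targets.items()}
        d["factors"] = list(self.factors)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "corr_targets" in d:
            ct = {}
            for k, v in d["corr_targets"].items():
                if isinstance(k, str):
                    a, b = k.split("|")
                else:
                    a, b = k
                ct[_pair_key(a, b)] = float(v)
            d["corr_targets"] = ct
        if "biases" in d:
            d["biases"] = {
                f: (b if isinstance(b, Biases) else Biases(**b))
                for f, b in d["biases"].items()
            }
        if "factors" in d:
            d["factors"] = tuple(d["factors"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generating parameters echoed alongside a synthetic population."""

    kind: str
    seed: int
    n_networks: int
    biases: dict[str, dict[str, float]] = field(default_factory=dict)
    parental_type_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    corr_targets: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    realised_missing_fraction: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _net_rng(seed: int, stream: int, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, i])


def generate_binary_population(
    config: GeneratorConfig,
) -> tuple[NetworkTable, GroundTruth]:
    """Draw a population of binary cultural traits under the additive model.

    Per network and factor: the Vertical-component trait ``v`` is
    Bernoulli(``trait_prev_vertical``); the Horizontal-component trait
    ``h`` copies ``v`` with probability ``parent_friend_corr`` and is
    otherwise independent; the student adopts the trait with probability
    ``other_trait + vertical * v + horizontal * h``.  Parents realise
    ``v`` (the second parent copies the first with probability
    ``couple_concordance``), friends realise ``h`` likewise.  Grandparents,
    when present, are independent draws at the vertical prevalence (they
    do not enter the additive model).  Scores are signed: +1 trait, -1 no
    trait.

    Returns the population and a :class:`GroundTruth` echoing the biases
    (including the complementarity-derived opposite-trait baseline) and
    the realised latent parental-type counts.
    """
    cfg = config
    # the binary generator covers exactly the factors that have biases
    factors = tuple(f for f in cfg.factors if f in cfg.biases) or tuple(cfg.biases)
    rows: list[tuple[str, str, str, float]] = []
    type_counts = {f: {"VH": 0, "Vh": 0, "vH": 0, "vh": 0} for f in factors}
    p_v, p_h = cfg.trait_prev_vertical, cfg.trait_prev_horizontal

    def signed(t: int) -> float:
        return 1.0 if t else -1.0

    for i in range(cfg.n_networks):
        rng = _net_rng(cfg.seed, 0, i)
        nid = f"net{i:06d}"
        present = {
            role: (p >= 1.0 or rng.random() < p)
            for role, p in cfg.role_presence.items()
        }
        for f in factors:
            b = cfg.biases[f]
            v = int(rng.random() < p_v)
            if rng.random() < cfg.parent_friend_corr:
                h = v
            else:
                h = int(rng.random() < p_h)
            p_student = b.other_trait + b.vertical * v + b.horizontal * h
            s = int(rng.random() < p_student)
            label = ("V" if v else "v") + ("H" if h else "h")
            type_counts[f][label] += 1

            mother = v
            father = v if rng.random() < cfg.couple_concordance else int(rng.random() < p_v)
            friend1 = h
            friend2 = h if rng.random() < cfg.friend_concordance else int(rng.random() < p_h)
            values = {
                Role.STUDENT.value: s,
                Role.STUDENT_T2.value: s,
                Role.MOTHER.value: mother,
                Role.FATHER.value: father,
                Role.FRIEND1.value: friend1,
                Role.FRIEND2.value: friend2,
            }
            for g in GRANDPARENT_ROLES:
                values[g.value] = int(rng.random() < p_v)
            for role in _ROLE_ORDER:
                if present.get(role, False):
                    rows.append((nid, role, f, signed(values[role])))

    df = pd.DataFrame(rows, columns=["network_id", "role", "factor", "score"])
    table = NetworkTable(df, factor_labels=tuple(factors))
    truth = GroundTruth(
        kind="binary",
        seed=cfg.seed,
        n_networks=cfg.n_networks,
        biases={
            f: {
                "vertical": cfg.biases[f].vertical,
                "horizontal": cfg.biases[f].horizontal,
                "other_trait": cfg.biases[f].other_trait,
                "other_opposite": cfg.biases[f].other_opposite,
            }
            for f in factors
        },
        parental_type_counts=type_counts,
    )
    return table, truth


def _build_correlation_matrix(cfg: GeneratorConfig) -> np.ndarray:
    k = len(_ROLE_ORDER)
    corr = np.full((k, k), cfg.baseline_corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    idx = {r: i for i, r in enumerate(_ROLE_ORDER)}
    for (a, b), r in cfg.corr_targets.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        # name the pair contributing most to the offending direction
        vec = np.abs(v[:, 0])
        i, j = np.argsort(vec)[-2:]
        raise ValueError(
            "correlation targets are not positive semi-definite; the pair "
            f"({_ROLE_ORDER[min(i, j)]!r}, {_ROLE_ORDER[max(i, j)]!r}) is the "
            "strongest contributor to the infeasible direction"
        )
    # eigen-based factor tolerates exact singularity
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return root


def generate_continuous_population(
    config: GeneratorConfig,
) -> tuple[NetworkTable, GroundTruth]:
    """Draw correlated continuous factor scores for a network population.

    Scores are standard normal marginally (zero mean — so dichotomising
    at 0 yields ~50% trait prevalence per role) with role-pair Pearson
    correlations equal to ``corr_targets`` in expectation (Gaussian
    copula with identity marginals).  Roles are present per
    ``role_presence``; ``missing_rate`` of the remaining scores are then
    blanked completely at random.
    """
    cfg = config
    root = _build_correlation_matrix(cfg)
    k = len(_ROLE_ORDER)
    n_f = len(cfg.factors)
    rows: list[tuple[str, str, str, float]] = []
    n_missing = 0
    for i in range(cfg.n_networks):
        rng = _net_rng(cfg.seed, 1, i)
        nid = f"net{i:06d}"
        present = [
            r for r in _ROLE_ORDER
            if cfg.role_presence[r] >= 1.0 or rng.random() < cfg.role_presence[r]
        ]
        z = rng.standard_normal((n_f, k))
        scores = z @ root.T  # (factor, role), unit variance, target corrs
        for fi, f in enumerate(cfg.factors):
            for r in present:
                val: float = float(scores[fi, _ROLE_ORDER.index(r)])
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    val = np.nan
                    n_missing += 1
                rows.append((nid, r, f, val))
    df = pd.DataFrame(rows, columns=["network_id", "role", "factor", "score"])
    table = NetworkTable(df, factor_labels=cfg.factors)
    truth = GroundTruth(
        kind="continuous",
        seed=cfg.seed,
        n_networks=cfg.n_networks,
        corr_targets={f"{a}|{b}": v for (a, b), v in cfg.corr_targets.items()},
        missing_rate=cfg.missing_rate,
        realised_missing_fraction=n_missing / max(len(rows), 1),
    )
    return table, truth
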