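"""Synthetic mother-infant communication data with known ground truth.

The generator emulates the structure of an observational study of
infant-directed gestural communication in orang-utan mothers: two species
(Bornean, Sumatran) crossed with two research settings (wild field sites,
zoos), seven study groups, and repeated binary outcomes per mother
(gestural redoings when the mother signals; satisfactory interaction
outcomes when the infant requests).  Responses are drawn from a
binomial-logit mixed model with individual and group random intercepts and,
optionally, correlated individual random slopes over a binary social
context — exactly the latent model the downstream analysis assumes — so
every estimate produced by the pipeline can be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GenerationError

SPECIES = ("bornean", "sumatran")
SETTINGS = ("wild", "captive")
DIRECTIONS = ("mother_to_infant", "infant_to_mother")

#: the seven coded social contexts (presumed goal of the signaller)
CONTEXT_LABELS = (
    "co-locomote",
    "food_share",
    "groom",
    "play_affiliate",
    "move_away",
    "sexual_contact",
    "stop_action",
)

#: focal (binarized) context per signalling direction: joint travel for
#: mother-signalled events, food begging for infant requests
FOCAL_CONTEXT = {
    "mother_to_infant": "co-locomote",
    "infant_to_mother": "food_share",
}

#: column order of the event-table interchange format
EVENT_COLUMNS = (
    "mother_id",
    "group_id",
    "species",
    "setting",
    "infant_age",
    "parity",
    "context",
    "context_binary",
    "direction",
    "gesture_type",
    "redo",
    "satisfactory",
)

BETA_TERMS = (
    "intercept",
    "setting_wild",
    "species_sumatran",
    "infant_age",
    "parity",
    "context",
)

# sub-stream tags so each generator op has its own reproducible stream
_POP_TAG, _EVENT_TAG, _REP_TAG = 11, 13, 17


@dataclass(frozen=True)
class GroupSpec:
    """One study group (field site or zoo): a species/setting cell member."""

    name: str
    species: str
    setting: str
    n_mothers: int


#: the study's seven groups: 13 Bornean (9 wild / 4 captive) and
#: 13 Sumatran mothers (8 wild / 5 captive) across 2 field sites + 5 zoos
STUDY_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("tuanan", "bornean", "wild", 9),
    GroupSpec("suaq", "sumatran", "wild", 8),
    GroupSpec("cologne", "bornean", "captive", 2),
    GroupSpec("munster", "bornean", "captive", 1),
    GroupSpec("apenheul", "bornean", "captive", 1),
    GroupSpec("zurich", "sumatran", "captive", 3),
    GroupSpec("hellabrunn", "sumatran", "captive", 2),
)


@dataclass
class PopulationConfig:
    """Roster and sampling-effort configuration.

    ``events_per_mother`` is the mean of a zero-truncated Poisson; mothers
    therefore contribute unbalanced sample sizes as in the field data.
    ``mother_signaller_prob`` splits events into mother-signalled versus
    infant-request direction; ``context_prob`` is the per-event probability
    of the focal binary context (joint travel / begging).
    """

    groups: tuple[GroupSpec, ...] = STUDY_GROUPS
    events_per_mother: float = 160.0
    mother_signaller_prob: float = 0.22
    context_prob: float = 0.35
    infant_age_range: tuple[int, int] = (1, 7)
    parity_range: tuple[int, int] = (1, 6)
    seed: int = 0

    @classmethod
    def from_cell_counts(
        cls, n_mothers_per_cell: Mapping[tuple[str, str], int], **kwargs
    ) -> "PopulationConfig":
        """Build a config with one group per non-empty species x setting cell."""
        groups = tuple(
            GroupSpec(f"{sp}_{st}", sp, st, int(n))
            for (sp, st), n in n_mothers_per_cell.items()
            if n
        )
        return cls(groups=groups, **kwargs)

    @property
    def n_mothers(self) -> int:
        return sum(g.n_mothers for g in self.groups)

    def validate(self) -> None:
        if not self.groups:
            raise ConfigurationError("groups: at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigurationError("groups: group names must be unique")
        for g in self.groups:
            if g.species not in SPECIES:
                raise ConfigurationError(f"groups[{g.name}].species: {g.species!r}")
            if g.setting not in SETTINGS:
                raise ConfigurationError(f"groups[{g.name}].setting: {g.setting!r}")
            if g.n_mothers < 0:
                raise ConfigurationError(f"groups[{g.name}].n_mothers: must be >= 0")
        if self.n_mothers == 0:
            raise ConfigurationError("groups: roster would be empty")
        if self.events_per_mother <= 0:
            raise ConfigurationError("events_per_mother: must be positive")
        for name in ("mother_signaller_prob", "context_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        for name in ("infant_age_range", "parity_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name}: invalid range ({lo}, {hi})")


@dataclass
class TruthParameters:
    """Ground-truth parameters of the latent binomial-logit mixed model.

    ``beta`` holds fixed effects on the logit scale, keyed by
    :data:`BETA_TERMS`.  Variance components: ``sigma2_id`` individual
    random intercepts, ``sigma2_group`` group random intercepts,
    ``sigma2_slope`` individual random slopes over the binary context,
    ``rho`` the intercept-slope correlation.  The defaults put latent
    individual repeatability at sigma2_id / (sigma2_id + sigma2_group +
    pi^2/3) ~= 0.10 with modest positive intercept-slope correlation.
    """

    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.0,
            "setting_wild": -0.3,
            "species_sumatran": 0.2,
            "infant_age": 0.05,
            "parity": -0.05,
            "context": 0.8,
        }
    )
    sigma2_id: float = 0.382
    sigma2_group: float = 0.15
    sigma2_slope: float = 1.0
    rho: float = 0.3

    def validate(self) -> None:
        missing = set(BETA_TERMS) - set(self.beta)
        if missing:
            raise ConfigurationError(f"beta: missing terms {sorted(missing)}")
        for name in ("sigma2_id", "sigma2_group", "sigma2_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: variance must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho: must lie in [-1, 1]")

    def intercept_slope_cov(self) -> np.ndarray:
        """2x2 covariance of the (intercept, slope) individual effects."""
        sd_i = np.sqrt(self.sigma2_id)
        sd_s = np.sqrt(self.sigma2_slope)
        off = self.rho * sd_i * sd_s
        cov = np.array([[self.sigma2_id, off], [off, self.sigma2_slope]])
        # guards against tiny negative eigenvalues at |rho| = 1
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-12:
            raise ConfigurationError("intercept/slope covariance not PSD")
        return cov


@dataclass
class RepertoireConfig:
    """Gesture-type pool configuration.

    A global pool of ``n_global_types`` types is split into a shared core
    (fraction ``setting_overlap`` available in both settings) and
    setting-exclusive remainders.  Each mother omits each available type
    independently with probability ``individual_idiosyncrasy``; her usage
    weights over kept types follow a symmetric Dirichlet with concentration
    ``usage_concentration`` (small values concentrate usage on few types).
    """

    n_global_types: int = 14
    setting_overlap: float = 0.7
    individual_idiosyncrasy: float = 0.15
    usage_concentration: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_global_types < 2:
            raise ConfigurationError("n_global_types: must be >= 2")
        for name in ("setting_overlap", "individual_idiosyncrasy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        if self.usage_concentration <= 0:
            raise ConfigurationError("usage_concentration: must be positive")


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw the mother roster: one row per mother with her covariates.

    Deterministic given ``config.seed``; per-cell counts follow the
    configured groups exactly.  Infant age and parity are sampled uniformly
    on their configured integer ranges, independently per mother.
    """
    config.validate()
    rng = _rng(config.seed, _POP_TAG)
    rows = []
    for g in config.groups:
        for i in range(g.n_mothers):
            rows.append(
                {
                    "mother_id": f"{g.name}_m{i + 1}",
                    "group_id": g.name,
                    "species": g.species,
                    "setting": g.setting,
                    "infant_age": int(
                        rng.integers(config.infant_age_range[0], config.infant_age_range[1] + 1)
                    ),
                    "parity": int(
                        rng.integers(config.parity_range[0], config.parity_range[1] + 1)
                    ),
                }
            )
    return pd.DataFrame(rows)


def _setting_pools(rconfig: RepertoireConfig) -> dict[str, list[str]]:
    """Split the global type pool into per-setting availability sets."""
    types = [f"g{idx:02d}" for idx in range(rconfig.n_global_types)]
    n_shared = int(round(rconfig.setting_overlap * rconfig.n_global_types))
    shared = types[:n_shared]
    rest = types[n_shared:]
    pools = {
        "wild": shared + rest[0::2],
        "captive": shared + rest[1::2],
    }
    return pools


def _mother_profiles(
    roster: pd.DataFrame, rconfig: RepertoireConfig, rng: np.random.Generator
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-mother kept types and Dirichlet usage weights."""
    pools = _setting_pools(rconfig)
    profiles: dict[str, tuple[list[str], np.ndarray]] = {}
    for row in roster.itertuples(index=False):
        pool = pools.get(row.setting, [])
        if not pool:
            raise GenerationError(
                f"empty gesture-type pool for setting {row.setting!r}"
            )
        keep = rng.random(len(pool)) >= rconfig.individual_idiosyncrasy
        kept = [t for t, k in zip(pool, keep) if k]
        if not kept:  # a repertoire must be nonempty
            kept = [pool[int(rng.integers(len(pool)))]]
        weights = rng.dirichlet(np.full(len(kept), rconfig.usage_concentration))
        profiles[row.mother_id] = (kept, weights)
    return profiles


@dataclass
class RealizedEffects:
    """Ground-truth random effects realized for one generated dataset."""

    mother: pd.DataFrame  # mother_id, intercept, slope
    group: pd.DataFrame  # group_id, intercept


def generate_events(
    roster: pd.DataFrame,
    truth: TruthParameters,
    config: PopulationConfig,
    rconfig: RepertoireConfig | None = None,
    n_events: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, RealizedEffects]:
    """Simulate the long-format event table from the latent logit model.

    Each event's linear predictor is

        eta = x'beta + u[mother] + v[group] + s[mother] * context_binary

    with (u, s) bivariate normal (variances ``sigma2_id``/``sigma2_slope``,
    correlation ``rho``) and v normal with variance ``sigma2_group``.  The
    binary response Bernoulli(expit(eta)) is recorded in the ``redo``
    column for mother-signalled events and in ``satisfactory`` for infant
    requests (the off-direction column is an independent draw at the same
    probability, so either analysis recovers the same truth).

    ``n_events`` optionally overrides the per-mother event count (mapping
    mother_id -> count); otherwise counts are zero-truncated Poisson with
    mean ``config.events_per_mother``.  Returns the event table and the
    realized random effects for parameter-recovery checks.
    """
    config.validate()
    truth.validate()
    if roster.empty:
        raise ConfigurationError("roster: must be nonempty")
    rng = _rng(config.seed, _EVENT_TAG)

    mothers = roster["mother_id"].tolist()
    groups = roster["group_id"].unique().tolist()

    cov = truth.intercept_slope_cov()
    # "eigh" tolerates the singular covariance of a zero slope variance
    us = rng.multivariate_normal(np.zeros(2), cov, size=len(mothers), method="eigh")
    v = rng.normal(0.0, np.sqrt(truth.sigma2_group), size=len(groups))
    u_m = dict(zip(mothers, us[:, 0]))
    s_m = dict(zip(mothers, us[:, 1]))
    v_g = dict(zip(groups, v))

    if rconfig is not None:
        rconfig.validate()
        profiles = _mother_profiles(roster, rconfig, _rng(rconfig.seed, _REP_TAG))
    else:
        generic = [f"g{idx:02d}" for idx in range(20)]
        profiles = {m: (generic, np.full(20, 1 / 20)) for m in mothers}

    b = truth.beta
    frames = []
    for row in roster.itertuples(index=False):
        if n_events is not None:
            k = int(n_events.get(row.mother_id, 0))
            if k <= 0:
                continue
        else:
            k = 0
            while k == 0:
                k = int(rng.poisson(config.events_per_mother))
        ctx = (rng.random(k) < config.context_prob).astype(int)
        is_mother = rng.random(k) < config.mother_signaller_prob
        direction = np.where(is_mother, DIRECTIONS[0], DIRECTIONS[1])

        eta = (
            b["intercept"]
            + b["setting_wild"] * (row.setting == "wild")
            + b["species_sumatran"] * (row.species == "sumatran")
            + b["infant_age"] * row.infant_age
            + b["parity"] * row.parity
            + b["context"] * ctx
            + u_m[row.mother_id]
            + v_g[row.group_id]
            + s_m[row.mother_id] * ctx
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        redo = (rng.random(k) < p).astype(int)
        satisfactory = (rng.random(k) < p).astype(int)

        # 7-level context label consistent with the binarization
        focal = np.where(
            is_mother, FOCAL_CONTEXT["mother_to_infant"], FOCAL_CONTEXT["infant_to_mother"]
        )
        labels = np.empty(k, dtype=object)
        for i in range(k):
            if ctx[i]:
                labels[i] = focal[i]
            else:
                others = [c for c in CONTEXT_LABELS if c != focal[i]]
                labels[i] = others[int(rng.integers(len(others)))]

        types, weights = profiles[row.mother_id]
        gestures = rng.choice(types, size=k, p=weights)

        frames.append(
            pd.DataFrame(
                {
                    "mother_id": row.mother_id,
                    "group_id": row.group_id,
                    "species": row.species,
                    "setting": row.setting,
                    "infant_age": row.infant_age,
                    "parity": row.parity,
                    "context": labels,
                    "context_binary": ctx,
                    "direction": direction,
                    "gesture_type": gestures,
                    "redo": redo,
                    "satisfactory": satisfactory,
                }
            )
        )
    if not frames:
        raise GenerationError("no events generated (all per-mother counts were 0)")
    events = pd.concat(frames, ignore_index=True)[list(EVENT_COLUMNS)]

    effects = RealizedEffects(
        mother=pd.DataFrame(
            {"mother_id": mothers, "intercept": us[:, 0], "slope": us[:, 1]}
        ),
        group=pd.DataFrame({"group_id": groups, "intercept": v}),
    )
    return events, effects


def generate_repertoires(
    roster: pd.DataFrame,
    rconfig: RepertoireConfig,
    n_instances_per_mother: int = 100,
) -> pd.DataFrame:
    """Draw per-mother gesture-type instance counts.

    Returns a wide table (rows = mothers, columns = gesture types, cells =
    counts; absent types are 0).  Every type a mother keeps receives at
    least one instance; remaining instances are multinomial over her usage
    weights.  Deterministic given ``rconfig.seed``.
    """
    rconfig.validate()
    if n_instances_per_mother < 1:
        raise ConfigurationError("n_instances_per_mother: must be >= 1")
    rng = _rng(rconfig.seed, _REP_TAG)
    profiles = _mother_profiles(roster, rconfig, rng)

    all_types = [f"g{idx:02d}" for idx in range(rconfig.n_global_types)]
    counts = pd.DataFrame(
        0, index=roster["mother_id"].tolist(), columns=all_types, dtype=int
    )
    for mother_id, (types, weights) in profiles.items():
        k = len(types)
        if n_instances_per_mother < k:
            chosen = rng.choice(k, size=n_instances_per_mother, replace=False)
            for j in chosen:
                counts.loc[mother_id, types[j]] = 1
            continue
        extra = rng.multinomial(n_instances_per_mother - k, weights)
        for j, t in enumerate(types):
            counts.loc[mother_id, t] = 1 + int(extra[j])
    counts.index.name = "mother_id"
    return counts


def write_events(events: pd.DataFrame, path) -> None:
    """Write the event table as delimited text (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    events.to_csv(path, sep=sep, index=False)


def write_truth(truth: TruthParameters, effects: RealizedEffects, path) -> None:
    """Export ground truth as a structured key/value text file (YAML)."""
    payload = {
        "beta": {k: float(v) for k, v in truth.beta.items()},
        "sigma2_id": float(truth.sigma2_id),
        "sigma2_group": float(truth.sigma2_group),
        "sigma2_slope": float(truth.sigma2_slope),
        "rho": float(truth.rho),
        "mother_effects": {
            r.mother_id: {"intercept": float(r.intercept), "slope": float(r.slope)}
            for r in effects.mother.itertuples(index=False)
        },
        "group_effects": {
            r.group_id: float(r.intercept) for r in effects.group.itertuples(index=False)
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
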