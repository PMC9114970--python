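"""Repertoire construction, Dice similarity and matrix permutation tests.

An individual's "customary" repertoire is the set of gesture types she used
at least twice, retained only if her total instance count over those types
exceeds 30 (undersampled individuals are excluded).  Pairwise similarity is
the Dice coefficient over type sets, D = 2|A & B| / (|A| + |B|).  The
within- versus between-setting contrast is assessed by permuting setting
labels over individuals while holding the dyadic matrix fixed, with the
asymmetric decision thresholds p <= 0.025 or p >= 0.975 (the permutation
null of a difference statistic need not be symmetric around zero).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContrastError, InputError

CONTRASTS = ("within_vs_between", "wild_within_vs_captive_within")

#: asymmetric two-sided decision thresholds on the one-tailed p
P_LOW, P_HIGH = 0.025, 0.975


@dataclass
class Repertoire:
    """One individual's filtered gesture-type instance counts."""

    mother_id: str
    type_counts: dict[str, int]

    @property
    def total_instances(self) -> int:
        return sum(self.type_counts.values())

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self.type_counts)


@dataclass
class DyadicSimilarityMatrix:
    """Symmetric Dice matrix over individuals with setting/species tags."""

    ids: list[str]
    values: np.ndarray
    settings: list[str]
    species: list[str]

    def subset(self, species: str) -> "DyadicSimilarityMatrix":
        idx = [i for i, s in enumerate(self.species) if s == species]
        return DyadicSimilarityMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            settings=[self.settings[i] for i in idx],
            species=[self.species[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PermutationResult:
    """Outcome of a dyadic matrix permutation test."""

    contrast: str
    statistic_observed: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    significant: bool
    exact: bool = False


def build_repertoires(
    events: pd.DataFrame,
    min_instances: int = 30,
    min_type_uses: int = 2,
) -> tuple[list[Repertoire], pd.DataFrame]:
    """Build filtered repertoires from an event table.

    Types used fewer than ``min_type_uses`` times by an individual are
    dropped first; the individual is then retained only if her remaining
    instance total strictly exceeds ``min_instances`` (an individual with
    exactly ``min_instances`` is excluded).  The caller is responsible for
    any direction filtering (mother-signalled acts only, in the study's
    usage).  Returns the repertoires plus an exclusion report with one row
    per dropped individual (columns mother_id, raw_instances,
    filtered_instances, reason).
    """
    if events.empty:
        raise InputError("event table is empty")
    repertoires: list[Repertoire] = []
    excluded = []
    for mother_id, sub in events.groupby("mother_id", sort=True):
        raw = sub["gesture_type"].value_counts()
        kept = raw[raw >= min_type_uses]
        total = int(kept.sum())
        if total > min_instances and len(kept) > 0:
            repertoires.append(
                Repertoire(str(mother_id), {str(t): int(c) for t, c in kept.items()})
            )
        else:
            excluded.append(
                {
                    "mother_id": str(mother_id),
                    "raw_instances": int(raw.sum()),
                    "filtered_instances": total,
                    "reason": f"<= {min_instances} instances after filtering",
                }
            )
    report = pd.DataFrame(
        excluded, columns=["mother_id", "raw_instances", "filtered_instances", "reason"]
    )
    return repertoires, report


def dice(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Dice coefficient of two repertoires' type sets: 2|A&B|/(|A|+|B|)."""
    a, b = rep_a.types, rep_b.types
    if not a or not b:
        raise InputError("dice: repertoires must be nonempty")
    return 2.0 * len(a & b) / (len(a) + len(b))


def similarity_matrix(
    repertoires: list[Repertoire], labels: pd.DataFrame
) -> DyadicSimilarityMatrix:
    """All-pairs Dice matrix.

    ``labels`` maps mother_id to setting and species (one row per mother,
    columns mother_id, setting, species); the diagonal is 1 by definition
    and excluded from all downstream statistics.
    """
    if len(repertoires) < 2:
        raise InputError("similarity_matrix: need at least 2 repertoires")
    lab = labels.drop_duplicates("mother_id").set_index("mother_id")
    ids = [r.mother_id for r in repertoires]
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dice(repertoires[i], repertoires[j])
    return DyadicSimilarityMatrix(
        ids=ids,
        values=values,
        settings=[str(lab.loc[m, "setting"]) for m in ids],
        species=[str(lab.loc[m, "species"]) for m in ids],
    )


def _contrast_stats(
    values: np.ndarray, labels: np.ndarray, contrast: str
) -> np.ndarray:
    """Vectorized contrast statistic for a batch of label vectors.

    ``labels`` has shape (B, n); returns B statistics.  For
    ``within_vs_between``: mean(within-setting dyads) - mean(between).
    For ``wild_within_vs_captive_within``: mean(within-wild) -
    mean(within-captive).
    """
    n = labels.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    vals = values[iu, ju]
    same = labels[:, iu] == labels[:, ju]
    if contrast == "within_vs_between":
        n_within = same.sum(axis=1)
        n_between = (~same).sum(axis=1)
        s_within = (same * vals).sum(axis=1)
        s_total = vals.sum()
        return s_within / n_within - (s_total - s_within) / n_between
    wild = labels == "wild"
    both_wild = wild[:, iu] & wild[:, ju]
    both_cap = (~wild[:, iu]) & (~wild[:, ju])
    return (both_wild * vals).sum(axis=1) / both_wild.sum(axis=1) - (
        both_cap * vals
    ).sum(axis=1) / both_cap.sum(axis=1)


def matrix_permutation_test(
    matrix: DyadicSimilarityMatrix,
    contrast: str = "within_vs_between",
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Permutation test of a setting contrast on a dyadic Dice matrix.

    Setting labels are permuted over individuals while the similarity
    matrix stays fixed, which preserves the dyadic dependence structure.
    The one-tailed p is the add-one-smoothed proportion of null statistics
    at least as large as the observed one, p = (1 + #{null >= obs}) /
    (n_perm + 1); significance is declared iff p <= 0.025 or p >= 0.975.
    Ties between null and observed statistics carry half weight in the
    Monte-Carlo p (continuous statistics tie with probability ~0; the
    half-weight keeps a completely signal-free matrix, where every
    permutation reproduces the observed statistic, at p ~ 0.5 instead of
    spuriously saturating a tail).  With ``exact=True`` all distinct label
    assignments are enumerated instead and p = #{null >= obs} /
    #assignments with full tie weight (the identity assignment is part of
    the null set), matching exhaustive-enumeration convention.
    """
    if contrast not in CONTRASTS:
        raise ContrastError(f"unknown contrast {contrast!r}")
    labels = np.asarray(matrix.settings, dtype=object)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ContrastError(
            "each setting class needs >= 2 individuals for the contrast"
        )
    observed = float(_contrast_stats(matrix.values, labels[None, :], contrast)[0])

    if exact:
        classes = sorted(set(labels))
        a = classes[0]
        pos_a = [i for i in range(len(labels)) if labels[i] == a]
        n_a = len(pos_a)
        assigns = []
        for combo in itertools.combinations(range(len(labels)), n_a):
            lab = np.array(
                [a if i in combo else classes[1] for i in range(len(labels))],
                dtype=object,
            )
            assigns.append(lab)
        null = _contrast_stats(matrix.values, np.stack(assigns), contrast)
        p = float(np.sum(null >= observed - 1e-12) / len(null))
        n_used = len(null)
        used_seed = None
        is_exact = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(labels) for _ in range(n_perm)])
        null = _contrast_stats(matrix.values, perms, contrast)
        greater = np.sum(null > observed + 1e-12)
        ties = np.sum(np.abs(null - observed) <= 1e-12)
        p = float((1 + greater + 0.5 * ties) / (n_perm + 1))
        n_used = n_perm
        used_seed = seed
        is_exact = False

    return PermutationResult(
        contrast=contrast,
        statistic_observed=observed,
        null_stats=np.asarray(null, dtype=float),
        p_value=p,
        n_perm=n_used,
        seed=used_seed,
        significant=bool(p <= P_LOW or p >= P_HIGH),
        exact=is_exact,
    )


def dyad_means(matrix: DyadicSimilarityMatrix) -> dict[str, float]:
    """Observed mean Dice per dyad class (within / between / per setting)."""
    labels = np.asarray(matrix.settings, dtype=object)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.values[iu, ju]
    same = labels[iu] == labels[ju]
    out = {
        "within": float(vals[same].mean()) if same.any() else math.nan,
        "between": float(vals[~same].mean()) if (~same).any() else math.nan,
    }
    for s in sorted(set(labels)):
        mask = (labels[iu] == s) & (labels[ju] == s)
        out[f"within_{s}"] = float(vals[mask].mean()) if mask.any() else math.nan
    return out


def repertoire_table(repertoires: list[Repertoire]) -> pd.DataFrame:
    """Wide export: rows = mothers, columns = gesture types, cells = counts."""
    all_types = sorted({t for r in repertoires for t in r.type_counts})
    data = {
        r.mother_id: [r.type_counts.get(t, 0) for t in all_types] for r in repertoires
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=all_types)
    out.index.name = "mother_id"
    return out
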