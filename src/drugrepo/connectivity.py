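"""Rank-based connectivity scoring.

Implements the Connectivity-Map style pattern matching used to decide
whether a candidate drug's expression response resembles that of known
anti-diabetic compounds (or opposes that of diabetogenic ones):

* a signed Kolmogorov–Smirnov "tag-set" enrichment statistic on the ranks
  of a gene set within a fully ranked genome-wide profile,
* per-instance connectivity scores combining an up-tag and a down-tag set,
* max-normalisation of instance scores to [-1, 1],
* a set-level enrichment of one perturbagen's instances within the
  connectivity-ordered instance list, with a permutation p-value,
* the direction-consistent support classification of candidate drugs
  against reference signatures of known polarity.

Profiles are strict rank permutations (rank 1 = most up-regulated gene).
Average/fractional ranks are deliberately rejected: the statistic is only
defined on a bijection onto 1..n, so ties in raw expression values must be
broken by stable input order before entering this module (see
:func:`ranks_from_expression`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

REFERENCE_DIRECTIONS = ("anti_diabetic", "glucose_improving", "diabetogenic")

__all__ = [
    "QuerySignature",
    "RankedProfile",
    "ConnectivityResult",
    "ks_enrichment",
    "instance_score",
    "scale_scores",
    "set_enrichment",
    "permutation_p",
    "classify_support",
    "connectivity_query",
    "ranks_from_expression",
]


@dataclass(frozen=True)
class QuerySignature:
    """An up/down tag-set query.

    Parameters
    ----------
    up_tags, down_tags
        Disjoint gene-identifier sets.  Either may be empty on its own,
        but not both; when both are non-empty the instance score combines
        the two one-sided statistics.
    """

    up_tags: frozenset = field(default_factory=frozenset)
    down_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "up_tags", frozenset(self.up_tags))
        object.__setattr__(self, "down_tags", frozenset(self.down_tags))
        if not self.up_tags and not self.down_tags:
            raise ValidationError("signature needs at least one non-empty tag set")
        overlap = self.up_tags & self.down_tags
        if overlap:
            raise ValidationError(
                f"up and down tag sets overlap: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class RankedProfile:
    """One treatment instance's full gene-rank permutation.

    ``ranks`` maps every gene in the universe to an integer rank in 1..n,
    rank 1 being the most up-regulated gene.
    """

    instance_id: str
    perturbagen: str
    ranks: Mapping[str, int]

    def __post_init__(self):
        n = len(self.ranks)
        values = sorted(self.ranks.values())
        if values != list(range(1, n + 1)):
            raise ValidationError(
                f"instance {self.instance_id!r}: ranks are not a permutation of 1..{n}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class ConnectivityResult:
    """Set-level association between a subject drug and a reference signature."""

    subject: str
    reference: str
    enrichment: float
    p_value: float
    n_instances: int
    direction_of_reference: str

    def __post_init__(self):
        if abs(self.enrichment) > 1 + 1e-12:
            raise ValidationError("enrichment must lie in [-1, 1]")
        if not (0 < self.p_value <= 1):
            raise ValidationError("p_value must lie in (0, 1]")
        if self.direction_of_reference not in REFERENCE_DIRECTIONS:
            raise ValidationError(
                f"unknown reference direction {self.direction_of_reference!r}"
            )


def _validate_positions(positions: Sequence[int], n: int, label: str) -> np.ndarray:
    arr = np.asarray(positions, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{label}: empty rank list")
    if not np.all(arr == np.floor(arr)):
        raise ValidationError(f"{label}: ranks must be integers (no ties allowed)")
    arr = arr.astype(np.int64)
    if np.any(np.diff(arr) <= 0):
        raise ValidationError(f"{label}: ranks must be strictly increasing")
    if arr[0] < 1 or arr[-1] > n:
        raise ValidationError(f"{label}: ranks must lie within 1..{n}")
    return arr


def ks_enrichment(tag_ranks: Sequence[int], n: int) -> float:
    """Signed KS enrichment of a tag set within a ranked list of length *n*.

    With the *t* tag positions ``V(1) < ... < V(t)`` among ``1..n``::

        a = max_j [ j/t - V(j)/n ]
        b = max_j [ V(j)/n - (j-1)/t ]

    and the score is ``a`` if ``a > b`` else ``-b``.  Positive scores mean
    the tags concentrate at the top of the list, negative at the bottom.
    """
    v = _validate_positions(tag_ranks, n, "tag_ranks")
    t = v.size
    j = np.arange(1, t + 1)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def _tag_positions(tags: Iterable[str], profile: RankedProfile) -> np.ndarray:
    ranks = []
    for tag in tags:
        try:
            ranks.append(profile.ranks[tag])
        except KeyError:
            raise ValidationError(
                f"tag {tag!r} absent from the profile gene universe"
            ) from None
    return np.sort(np.asarray(ranks, dtype=np.int64))


def instance_score(signature: QuerySignature, profile: RankedProfile) -> float:
    """Connectivity score of one instance against an up/down signature.

    ``ks_up`` is the enrichment of the up tags, ``ks_down`` of the down
    tags.  When the two statistics share a sign the profile is not
    discriminating between the tag sets and the score is exactly 0;
    otherwise the score is ``ks_up - ks_down`` (bounded in [-2, 2]).  A
    one-sided signature (only up or only down tags) scores with the single
    statistic, down tags negated.
    """
    n = profile.n_genes
    if not signature.up_tags:
        return -ks_enrichment(_tag_positions(signature.down_tags, profile), n)
    if not signature.down_tags:
        return ks_enrichment(_tag_positions(signature.up_tags, profile), n)
    ks_up = ks_enrichment(_tag_positions(signature.up_tags, profile), n)
    ks_down = ks_enrichment(_tag_positions(signature.down_tags, profile), n)
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def scale_scores(raw_scores: Sequence[float]) -> np.ndarray:
    """Normalise raw instance scores to [-1, 1].

    Positive scores are divided by the maximum positive score, negative
    scores by the magnitude of the minimum negative score; zeros stay
    zero.  Rank order is preserved.
    """
    scores = np.asarray(raw_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("scale_scores: empty score list")
    out = scores.copy()
    pos = scores > 0
    neg = scores < 0
    if pos.any():
        out[pos] = scores[pos] / scores[pos].max()
    if neg.any():
        out[neg] = scores[neg] / abs(scores[neg].min())
    return out


def set_enrichment(member_positions: Sequence[int], n_total: int) -> float:
    """KS enrichment of one perturbagen's instances in the ordered instance list.

    Identical statistic to :func:`ks_enrichment`, applied to the 1-based
    positions of the perturbagen's instances within the
    connectivity-ordered list of all ``n_total`` instances.
    """
    return ks_enrichment(member_positions, n_total)


def permutation_p(
    observed: float, t: int, n_total: int, n_perm: int = 10000, *, seed: int
) -> float:
    """Two-sided permutation p-value for a set-level enrichment score.

    Draws ``n_perm`` uniform random t-subsets of ``1..n_total``, recomputes
    the set enrichment for each, and returns the add-one corrected tail
    probability ``(1 + #{|null| >= |observed|}) / (1 + n_perm)``.
    Deterministic for a fixed *seed*.
    """
    if t >= n_total:
        raise ValidationError(f"t={t} must be smaller than n_total={n_total}")
    if t < 1:
        raise ValidationError("t must be at least 1")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    threshold = abs(observed) - 1e-12  # guard fp noise in >= comparison
    exceed = 0
    for _ in range(n_perm):
        draw = np.sort(rng.choice(n_total, size=t, replace=False) + 1)
        if abs(ks_enrichment(draw, n_total)) >= threshold:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def classify_support(
    results: Iterable[ConnectivityResult], alpha: float = 0.05
) -> dict:
    """Classify each subject drug as supported / data_no_link / no_data.

    A drug is *supported* when at least one of its results is significant
    (``p < alpha``) and direction-consistent: positive enrichment against
    an anti-diabetic or glucose-improving reference, or negative
    enrichment against a diabetogenic reference.  Drugs with results but
    no qualifying one are *data_no_link*.  Subjects passed in with an
    empty result list map to *no_data*.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    per_drug: dict[str, list[ConnectivityResult]] = {}
    for res in results:
        per_drug.setdefault(res.subject, []).append(res)
    out = {}
    for drug, rows in per_drug.items():
        if not rows:
            out[drug] = "no_data"
            continue
        supported = any(
            r.p_value < alpha
            and (
                (r.enrichment > 0 and r.direction_of_reference in
                 ("anti_diabetic", "glucose_improving"))
                or (r.enrichment < 0 and r.direction_of_reference == "diabetogenic")
            )
            for r in rows
        )
        out[drug] = "supported" if supported else "data_no_link"
    return out


def connectivity_query(
    signature: QuerySignature,
    profiles: Sequence[RankedProfile],
    *,
    n_perm: int = 10000,
    seed: int,
    reference_label: str = "signature",
    direction_of_reference: str = "anti_diabetic",
) -> pd.DataFrame:
    """Score every perturbagen in a profile collection against a signature.

    Pipeline: instance scores -> max-normalisation -> instances ordered by
    descending scaled score (stable for ties) -> per-perturbagen set
    enrichment of its instance positions -> permutation p-value.  Returns
    one row per perturbagen with columns matching
    :class:`ConnectivityResult`.
    """
    if not profiles:
        raise ValidationError("connectivity_query: no profiles supplied")
    raw = np.array([instance_score(signature, p) for p in profiles])
    scaled = scale_scores(raw)
    seed_rng = np.random.default_rng(seed)
    # descending order, ties broken by a seeded random key: the same-sign
    # rule puts many null instances at exactly 0, and a stable tie order
    # would bias set-level positions (and hence permutation p-values)
    # toward the input order of the profile collection
    jitter = seed_rng.permutation(len(profiles))
    order = np.lexsort((jitter, -scaled))
    position = np.empty(len(profiles), dtype=np.int64)
    position[order] = np.arange(1, len(profiles) + 1)

    members: dict[str, list[int]] = {}
    for i, prof in enumerate(profiles):
        members.setdefault(prof.perturbagen, []).append(int(position[i]))
    rows = []
    for pert in sorted(members):
        positions = sorted(members[pert])
        score = set_enrichment(positions, len(profiles))
        sub_seed = int(seed_rng.integers(0, 2**31 - 1))
        p = permutation_p(score, len(positions), len(profiles), n_perm, seed=sub_seed)
        rows.append(
            {
                "subject": pert,
                "reference": reference_label,
                "enrichment": score,
                "p_value": p,
                "n_instances": len(positions),
                "direction_of_reference": direction_of_reference,
            }
        )
    return pd.DataFrame(rows)


def ranks_from_expression(values: Mapping[str, float]) -> dict[str, int]:
    """Convert raw expression values to a strict rank permutation.

    Rank 1 is the largest value (most up-regulated).  Ties are broken by
    stable input order — never by average ranks, which would break the
    permutation invariant the KS statistic requires.
    """
    genes = list(values)
    order = np.argsort(-np.asarray([values[g] for g in genes]), kind="stable")
    return {genes[i]: int(r) for r, i in enumerate(order, start=1)}
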