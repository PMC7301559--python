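"""Characteristic-direction signatures and cosine matching.

The characteristic direction separates two Gaussian classes with a shared
covariance: v ∝ Σ^{-1} (μ1 - μ0), unit-normalized (the class priors only
shift the decision constant and drop out of the direction).  Two signatures
are compared by the cosine of the angle between them on their shared gene
universe; raw cosines are normalized against an empirical null of cosines to
randomly drawn directions, and |normalized score| beyond the two-sided 5%
normal threshold (1.96) flags a candidate match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import holm_sidak_adjust
from .datatypes import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledExpression",
    "CharacteristicDirection",
    "NullDistribution",
    "characteristic_direction",
    "cosine_distance",
    "build_null",
    "normalize_against_null",
    "call_lincs_hits",
]


@dataclass
class LabeledExpression:
    """Expression matrix with binary case/control sample labels."""

    expr: ExpressionMatrix
    labels: np.ndarray  # 0 = control, 1 = case, one per sample

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if len(self.labels) != self.expr.n_samples:
            raise ValidationError("label length does not match sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be 0 (control) or 1 (case)")
        if (self.labels == 0).sum() < 2 or (self.labels == 1).sum() < 2:
            raise ValidationError("each class needs at least 2 samples")


@dataclass
class CharacteristicDirection:
    """Unit-norm gene-space direction separating cases from controls."""

    gene_ids: list[str]
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        if len(self.gene_ids) != len(self.direction):
            raise ValidationError("gene id / direction length mismatch")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-10:
            raise ValidationError("characteristic direction is not unit-norm")


@dataclass
class NullDistribution:
    """Empirical null sample of cosine distances to a target signature."""

    samples: np.ndarray
    mean: float
    sd: float
    n_samples: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValidationError("null distribution needs >= 100 samples")
        if self.sd <= 0:
            raise ValidationError("null distribution has zero spread")


def characteristic_direction(
    data: LabeledExpression, shrinkage: float = 0.5
) -> CharacteristicDirection:
    """Shared-covariance whitened mean-difference direction.

    The pooled within-class covariance is shrunk toward a scaled identity,
    ``(1-s)·S + s·(tr S / p)·I``; with ``shrinkage=0`` the raw pooled
    covariance is used and must be nonsingular.  The direction points from
    controls toward cases.
    """
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    x = data.expr.values
    mask1 = data.labels == 1
    x0, x1 = x[:, ~mask1], x[:, mask1]
    n0, n1 = x0.shape[1], x1.shape[1]
    delta = x1.mean(axis=1) - x0.mean(axis=1)
    if np.allclose(delta, 0):
        raise ValidationError("degenerate signature: class means are identical")
    d0 = x0 - x0.mean(axis=1, keepdims=True)
    d1 = x1 - x1.mean(axis=1, keepdims=True)
    pooled = (d0 @ d0.T + d1 @ d1.T) / (n0 + n1 - 2)
    p = pooled.shape[0]
    sigma = (1 - shrinkage) * pooled + shrinkage * (np.trace(pooled) / p) * np.eye(p)
    try:
        v = np.linalg.solve(sigma, delta)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular shared covariance; use shrinkage > 0"
        ) from exc
    nrm = np.linalg.norm(v)
    # an exactly rank-deficient matrix may "solve" without raising; verify
    if (
        not np.isfinite(nrm)
        or nrm == 0
        or not np.allclose(sigma @ v, delta, atol=1e-6 * max(1.0, np.abs(delta).max()))
    ):
        raise ValidationError("singular shared covariance; use shrinkage > 0")
    return CharacteristicDirection(list(data.expr.gene_ids), v / nrm)


def cosine_distance(v1: CharacteristicDirection, v2: CharacteristicDirection) -> float:
    """Cosine similarity on the shared gene universe, in [-1, 1].

    Both vectors are restricted to the intersection of their gene lists (in
    ``v1`` order) and re-normalized before the inner product.
    """
    if v1.gene_ids == v2.gene_ids:
        a, b = v1.direction, v2.direction
    else:
        in2 = {g: i for i, g in enumerate(v2.gene_ids)}
        common = [g for g in v1.gene_ids if g in in2]
        if not common:
            raise ValidationError("signatures share no genes")
        in1 = {g: i for i, g in enumerate(v1.gene_ids)}
        a = v1.direction[[in1[g] for g in common]]
        b = v2.direction[[in2[g] for g in common]]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("signature vanishes on the shared gene universe")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def build_null(
    target: CharacteristicDirection,
    n: int = 10_000,
    seed: int | None = None,
    pool: list | None = None,
) -> NullDistribution:
    """Empirical null of cosine distances to ``target``.

    With a ``pool`` of reference signatures, ``n`` of them are resampled with
    replacement; otherwise isotropic random unit vectors on the target's gene
    universe are drawn (for which the cosine has mean 0 and SD ≈ 1/sqrt(p)).
    """
    if n < 100:
        raise ValueError("null sample size must be >= 100")
    rng = np.random.default_rng(seed)
    if pool is not None:
        if len(pool) == 0:
            raise ValueError("empty signature pool")
        idx = rng.integers(0, len(pool), size=n)
        samples = np.array([cosine_distance(pool[i], target) for i in idx])
    else:
        p = len(target.gene_ids)
        draws = rng.standard_normal((n, p))
        draws /= np.linalg.norm(draws, axis=1, keepdims=True)
        samples = draws @ target.direction
    return NullDistribution(samples, float(samples.mean()), float(samples.std(ddof=1)), n, seed)


def normalize_against_null(d: float, null: NullDistribution) -> float:
    """Standardize a cosine distance by the empirical null's mean and SD."""
    if null.sd <= 0:
        raise ValidationError("null distribution has zero spread")
    return (d - null.mean) / null.sd


def call_lincs_hits(
    perturbation_sigs: dict,
    disease_sigs: dict,
    n_null: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
    adjust: bool = True,
    pool: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Call perturbation/disease signature matches against an empirical null.

    For every (perturbation, disease) pair the cosine distance is normalized
    by a per-disease null (built from ``pool`` or isotropic directions,
    seeded).  Two-sided normal p-values of the normalized scores are
    Holm–Sidak adjusted across each perturbation's pairs (its family of
    disease-signature replicates); a perturbation is a hit when any pair
    survives at ``alpha``.  With ``adjust=False`` the bare |score| > 1.96
    rule is applied instead.

    Returns the per-pair table and a perturbation -> hit mapping.
    """
    if not perturbation_sigs or not disease_sigs:
        raise ValueError("perturbation and disease signature lists must be nonempty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    threshold = norm.isf(alpha / 2)  # 1.959964 at alpha=0.05
    seeds = np.random.SeedSequence(seed).generate_state(len(disease_sigs))
    nulls = {
        name: build_null(sig, n=n_null, seed=int(s), pool=pool)
        for (name, sig), s in zip(sorted(disease_sigs.items()), seeds)
    }
    rows = []
    for pert_name, pert in sorted(perturbation_sigs.items()):
        for dis_name in sorted(disease_sigs):
            d = cosine_distance(pert, disease_sigs[dis_name])
            score = normalize_against_null(d, nulls[dis_name])
            rows.append(
                dict(perturbation=pert_name, disease=dis_name,
                     distance=d, normalized=score,
                     p=max(2 * norm.sf(abs(score)), np.finfo(float).tiny))
            )
    table = pd.DataFrame(rows)
    hits: dict = {}
    adj_col = np.full(len(table), np.nan)
    for pert_name, idx in table.groupby("perturbation").groups.items():
        sub = table.loc[idx]
        if adjust:
            p_adj = holm_sidak_adjust(sub["p"].to_numpy())
            adj_col[np.asarray(idx)] = p_adj
            hits[pert_name] = bool((p_adj < alpha).any())
        else:
            hits[pert_name] = bool((sub["normalized"].abs() > threshold).any())
    table["p_adjusted"] = adj_col
    return table, hits
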