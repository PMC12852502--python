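"""Monte Carlo null models for synchrony and per-taxon contributions.

The null model permutes each taxon's time series independently across
years (within-column permutation).  This preserves every species'
marginal abundance distribution while destroying cross-species temporal
correlation — the randomization used by the standard community-synchrony
software.

Two procedures are built on it:

* a community-level test: all columns are permuted in each of
  ``n_reps`` (default 999) randomizations, and a one-tailed add-one
  p-value asks whether the observed community is *more* synchronous
  than the null;
* per-taxon contributions: one taxon's column is permuted (default 100
  times) while all others are held fixed; the z-score of the observed
  synchrony against that taxon-specific null measures how much the
  taxon fluctuates with the rest of the community.  |z| > 1.96 is the
  conventional significance cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import CommunityMatrix
from .synchrony import SynchronyResult, community_synchrony, phi_ratio_stack

Z_CRIT_DEFAULT = 1.96


@dataclass(frozen=True)
class TaxonContribution:
    """One taxon's standardized contribution to community synchrony.

    ``z`` is (observed phi − mean null phi) / SD(null phi) under
    randomization of this taxon's column only.  ``classification`` is
    ``positive`` (z > z_crit: the taxon fluctuates with the community),
    ``negative`` (z < −z_crit: it fluctuates against it),
    ``nonsignificant``, or ``degenerate`` when the null distribution has
    zero spread (e.g. a constant column), in which case z is reported as 0.
    """

    taxon: str
    z: float
    phi_obs: float
    null_mean: float
    null_sd: float
    n_reps: int
    classification: str


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def permute_within_columns(
    matrix: CommunityMatrix,
    rng: np.random.Generator,
    columns: Sequence[str] | None = None,
) -> CommunityMatrix:
    """Independently permute the selected taxa's values across years.

    ``columns=None`` permutes every taxon.  Each selected column keeps
    its multiset of values; unselected columns are untouched.
    """
    X = matrix.X.copy()
    if columns is None:
        idx = np.arange(matrix.n_taxa)
    else:
        idx = np.array([matrix.column(t) for t in columns], dtype=int)
    for j in idx:
        X[:, j] = rng.permutation(X[:, j])
    return matrix.with_X(X)


def _null_phis_all_columns(
    X: np.ndarray, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """phi of ``n_reps`` randomizations with every column permuted."""
    T, N = X.shape
    stack = rng.permuted(np.broadcast_to(X, (n_reps, T, N)), axis=1)
    return phi_ratio_stack(stack)


def community_null_test(
    matrix: CommunityMatrix, n_reps: int = 999, seed: int | None = None
) -> SynchronyResult:
    """Test observed synchrony against the within-column permutation null.

    Returns the observed SynchronyResult augmented with the one-tailed
    add-one p-value P(phi_null >= phi_obs) = (1 + #{phi_null >= phi_obs})
    / (n_reps + 1), plus the null mean and SD.  The smallest attainable
    p is therefore 1/(n_reps + 1).
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    obs = community_synchrony(matrix)  # raises on degenerate matrices
    rng = _rng(seed)
    null = _null_phis_all_columns(matrix.X, n_reps, rng)
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= obs.phi)) / (n_reps + 1.0)
    return SynchronyResult(
        phi=obs.phi,
        var_total=obs.var_total,
        sd_species=obs.sd_species,
        n_taxa=obs.n_taxa,
        n_years=obs.n_years,
        p_value=float(p),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if null.size > 1 else 0.0,
        n_reps=n_reps,
        seed=seed,
    )


def _classify(z: float, degenerate: bool, z_crit: float) -> str:
    if degenerate:
        return "degenerate"
    if z > z_crit:
        return "positive"
    if z < -z_crit:
        return "negative"
    return "nonsignificant"


def taxon_contribution(
    matrix: CommunityMatrix,
    taxon: str,
    n_reps: int = 100,
    seed=None,
    z_crit: float = Z_CRIT_DEFAULT,
) -> TaxonContribution:
    """z-score of one taxon's contribution to community synchrony.

    The taxon's column is permuted ``n_reps`` times while all other taxa
    stay fixed; community synchrony is recomputed for each randomization.
    Permuting a column leaves its SD unchanged, so only the numerator
    (variance of the community total) varies across the null.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    obs = community_synchrony(matrix)
    j = matrix.column(taxon)
    rng = _rng(seed)

    X = matrix.X
    col = X[:, j]
    if np.ptp(col) == 0.0:
        # permuting a constant column cannot change the matrix: the null
        # is a point mass and the z-score is undefined
        return TaxonContribution(
            taxon=taxon,
            z=0.0,
            phi_obs=obs.phi,
            null_mean=obs.phi,
            null_sd=0.0,
            n_reps=n_reps,
            classification="degenerate",
        )
    rest_total = X.sum(axis=1) - col
    denom = obs.sd_species.sum() ** 2
    perms = rng.permuted(np.broadcast_to(col, (n_reps, len(col))), axis=1)
    null_phi = (rest_total[None, :] + perms).var(axis=1, ddof=1) / denom

    null_mean = float(null_phi.mean())
    null_sd = float(null_phi.std(ddof=1)) if n_reps > 1 else 0.0
    degenerate = null_sd == 0.0
    z = 0.0 if degenerate else float((obs.phi - null_mean) / null_sd)
    return TaxonContribution(
        taxon=taxon,
        z=z,
        phi_obs=obs.phi,
        null_mean=null_mean,
        null_sd=null_sd,
        n_reps=n_reps,
        classification=_classify(z, degenerate, z_crit),
    )


def all_contributions(
    matrix: CommunityMatrix,
    n_reps: int = 100,
    seed: int | None = None,
    z_crit: float = Z_CRIT_DEFAULT,
) -> list[TaxonContribution]:
    """Contribution z-scores for every taxon, in ``matrix.taxa`` order.

    Each taxon draws from its own reproducible substream of the master
    seed, so results do not depend on evaluation order and adding a
    filter upstream cannot silently shift another taxon's null.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(matrix.n_taxa)
    return [
        taxon_contribution(matrix, taxon, n_reps=n_reps, seed=children[j], z_crit=z_crit)
        for j, taxon in enumerate(matrix.taxa)
    ]
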