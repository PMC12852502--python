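"""The Loreau–de Mazancourt community synchrony statistic.

For a community of N species with annual abundance series x_i(t),
community synchrony is the variance ratio

    phi = Var( sum_i x_i(t) ) / ( sum_i SD(x_i) )^2

bounded in [0, 1]: phi = 1 when all species fluctuate in perfect
proportion, phi -> 0 when fluctuations cancel (compensatory dynamics).
The ratio is invariant to the variance divisor (T vs T-1) as long as
numerator and denominator use the same one; this package uses the
sample divisor T-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCommunityError, ValidationError
from .io import CommunityMatrix


@dataclass(frozen=True)
class SynchronyResult:
    """Community synchrony with its building blocks and (optionally) a null test.

    ``var_total`` is the temporal variance of summed community abundance;
    ``sd_species`` the per-taxon temporal standard deviations.  The null
    fields are populated by :func:`streamsync.resampling.community_null_test`.
    """

    phi: float
    var_total: float
    sd_species: np.ndarray
    n_taxa: int
    n_years: int
    p_value: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_reps: int | None = None
    seed: int | None = None


def phi_ratio(X: np.ndarray, ddof: int = 1) -> float:
    """Synchrony ratio of a (T, N) abundance matrix.

    Taxa with zero temporal variance contribute nothing to either the
    numerator's variability or the denominator sum.  Raises
    DegenerateCommunityError when every taxon is constant (0/0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D (years x taxa) matrix")
    var_total = X.sum(axis=1).var(ddof=ddof)
    sd_sum = X.std(axis=0, ddof=ddof).sum()
    if sd_sum == 0.0:
        raise DegenerateCommunityError(
            "all taxa are constant through time; synchrony is 0/0"
        )
    return float(var_total / sd_sum**2)


def phi_ratio_stack(stack: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Vectorized :func:`phi_ratio` over a (R, T, N) stack of matrices.

    Used by the resampling layer, where R is the number of Monte Carlo
    randomizations.  Degenerate members yield NaN rather than raising.
    """
    stack = np.asarray(stack, dtype=float)
    var_total = stack.sum(axis=2).var(axis=1, ddof=ddof)
    sd_sum = stack.std(axis=1, ddof=ddof).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return var_total / sd_sum**2


def community_synchrony(matrix: CommunityMatrix, ddof: int = 1) -> SynchronyResult:
    """Compute community synchrony for one site's annual matrix."""
    X = matrix.X
    phi = phi_ratio(X, ddof=ddof)
    return SynchronyResult(
        phi=phi,
        var_total=float(X.sum(axis=1).var(ddof=ddof)),
        sd_species=X.std(axis=0, ddof=ddof),
        n_taxa=matrix.n_taxa,
        n_years=matrix.n_years,
    )


def expected_phi_compound_symmetry(n_taxa: int, rho: float) -> float:
    """Analytic synchrony of an equal-variance, constant-correlation community.

    If N series have equal variance and every pair correlates at rho,
    then phi = (1 + (N - 1) rho) / N.  Serves as a closed-form oracle for
    simulation tests: rho = 0 gives 1/N, rho = 1 gives 1.
    """
    if n_taxa < 1:
        raise ValidationError("n_taxa must be >= 1")
    if n_taxa == 1:
        if not (-1.0 <= rho <= 1.0):
            raise ValidationError("rho must be in [-1, 1]")
        return 1.0
    lo = -1.0 / (n_taxa - 1)
    if not (lo <= rho <= 1.0):
        raise ValidationError(
            f"rho={rho} outside the positive-semidefinite range "
            f"[{lo:.4f}, 1] for {n_taxa} taxa"
        )
    return (1.0 + (n_taxa - 1) * rho) / n_taxa
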