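"""Adaptive "unassigned" calling via a 1-D Gaussian mixture on the
ensemble uncertainty score.

When the query contains unseen cell types, the uncertainty score ``m``
tends to be multimodal: confident shared-type cells pile up near 0 and
unseen-type cells near 1.  A univariate Gaussian mixture with 1–5
components is fit to ``m``; the component count is chosen by AIC.  One
component means no evidence of an uncertain subpopulation and nothing is
flagged.  Otherwise every mixture group whose mean score is >= 0.6 is
flagged, and the group with the largest mean is always flagged; member
cells become "unassigned".
"""

from __future__ import annotations

import numpy as np
from sklearn.mixture import GaussianMixture

from .containers import ThresholdDiagnostics

DEFAULT_MEAN_CUTOFF = 0.6


def fit_gmm_1d(
    m: np.ndarray,
    k_range: range = range(1, 6),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[GaussianMixture, dict[int, float]]:
    """Fit mixtures for each component count and keep the AIC minimizer.

    Non-converging component counts are recorded as skipped; ties in AIC
    resolve to the smaller model.
    """
    m = np.asarray(m, dtype=np.float64).reshape(-1, 1)
    if m.shape[0] < 10:
        raise ValueError("need at least 10 cells to fit the mixture")
    aics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=n_init,
                reg_covar=1e-6,
                random_state=seed,
                max_iter=200,
            ).fit(m)
        except ValueError:
            continue
        if not gm.converged_:
            continue
        aics[k] = float(gm.aic(m))
        fits[k] = gm
    if not fits:
        raise RuntimeError("Gaussian mixture failed to converge for every k")
    chosen = min(aics, key=lambda k: (aics[k], k))
    return fits[chosen], aics


def assign_groups(mixture: GaussianMixture, m: np.ndarray) -> np.ndarray:
    """Posterior-argmax group per cell; posterior ties go to the group
    with the larger mean."""
    m = np.asarray(m, dtype=np.float64).reshape(-1, 1)
    post = mixture.predict_proba(m)
    means = mixture.means_.ravel()
    # reorder columns by ascending mean, argmax on the reversed view so a
    # tie lands on the larger-mean component
    order = np.argsort(means, kind="stable")
    post_sorted = post[:, order]
    k = post_sorted.shape[1]
    rev_arg = np.argmax(post_sorted[:, ::-1], axis=1)
    return order[k - 1 - rev_arg]


def identify_unassigned(
    groups: np.ndarray,
    m: np.ndarray,
    mixture: GaussianMixture,
    aic_per_k: dict[int, float],
    mean_cutoff: float = DEFAULT_MEAN_CUTOFF,
    strict_cutoff_only: bool = False,
) -> tuple[np.ndarray, ThresholdDiagnostics]:
    """Flag cells in uncertain mixture groups.

    With a single component nothing is flagged.  Otherwise the uncertain
    groups are those with mean(m) >= ``mean_cutoff`` plus — unless
    ``strict_cutoff_only`` — the group with the largest mean.
    """
    m = np.asarray(m, dtype=np.float64)
    k = mixture.n_components
    present = np.unique(groups)
    group_means = np.array(
        [m[groups == g].mean() if np.any(groups == g) else np.nan for g in range(k)]
    )

    if k == 1:
        uncertain: list[int] = []
    else:
        uncertain = [
            int(g) for g in present if group_means[g] >= mean_cutoff
        ]
        if not strict_cutoff_only:
            top = int(present[np.nanargmax(group_means[present])])
            if top not in uncertain:
                uncertain.append(top)
        uncertain.sort()

    mask = np.isin(groups, uncertain)
    implied = float(m[mask].min()) if mask.any() else None
    diag = ThresholdDiagnostics(
        chosen_k=k,
        aic_per_k=aic_per_k,
        group_means=group_means,
        uncertain_groups=uncertain,
        implied_threshold=implied,
    )
    return mask, diag


def finalize_annotation(vote_labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged cells' labels with "unassigned"."""
    if len(vote_labels) != len(mask):
        raise ValueError("labels and mask length mismatch")
    out = np.asarray(vote_labels, dtype=object).copy()
    out[np.asarray(mask, dtype=bool)] = "unassigned"
    return out


def call_unassigned(
    m: np.ndarray,
    seed: int = 0,
    mean_cutoff: float = DEFAULT_MEAN_CUTOFF,
    strict_cutoff_only: bool = False,
) -> tuple[np.ndarray, ThresholdDiagnostics]:
    """Full Module-V pass: fit, group, flag."""
    mixture, aics = fit_gmm_1d(m, seed=seed)
    groups = assign_groups(mixture, m)
    return identify_unassigned(
        groups, m, mixture, aics,
        mean_cutoff=mean_cutoff, strict_cutoff_only=strict_cutoff_only,
    )
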