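"""Procrustes ANOVA for object symmetry: individual, side, individual x side, error.

The variance of the aligned coordinates is decomposed into four strata:

* **individual** — variation of individuals' symmetric shape around the
  consensus (``SS = r * sum_i ||mean symmetric deviation of i||^2``);
* **side (DA)** — directional asymmetry, the shared left-right offset
  (``SS = n * r * ||da_vector||^2``);
* **individual x side (FA)** — fluctuating asymmetry, individual departures
  from the shared asymmetry (``SS = r * sum_i ||mean asymmetry of i - DA||^2``);
* **error** — replicate digitizing scatter around each individual's mean, in
  both components.

Degrees of freedom are counted in shape-space dimensions: with ``p``
bilateral pairs and ``u`` midline landmarks in 3-D, the symmetric subspace
has ``d_sym = 3p + 2u - 4`` dimensions and the asymmetric subspace
``d_asym = 3p + u - 3``.  The individual and side effects are tested over
the interaction (FA) mean square, and the interaction over error — the
standard ladder for judging FA against digitizing noise.  p-values are
parametric (F distribution at the Procrustes df).  Percent variation is the
effect's share of the total sum of squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .symmetry import SymmetryDecomposition

logger = logging.getLogger(__name__)

EFFECT_ORDER = ("individual", "side", "individual_x_side", "error")
EFFECT_LABELS = {
    "individual": "Individual",
    "side": "Side (DA)",
    "individual_x_side": "Individual*Side (FA)",
    "error": "Error",
}


def anova_dfs(n: int, r: int, p: int, u: int) -> tuple[int, int, int, int]:
    """Closed-form Procrustes ANOVA degrees of freedom for 3-D object symmetry.

    Returns ``(df_individual, df_side, df_interaction, df_error)`` for ``n``
    individuals, ``r`` replicate digitizations, ``p`` bilateral pairs and
    ``u`` midline landmarks:

    ``df_individual = (n-1) * d_sym``, ``df_side = d_asym``,
    ``df_interaction = (n-1) * d_asym``, ``df_error = (r-1) * n *
    (d_sym + d_asym)`` with ``d_sym = 3p + 2u - 4`` and
    ``d_asym = 3p + u - 3``.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if p < 1:
        raise ValueError("need at least 1 bilateral pair")
    if r < 2:
        raise ValueError(
            "with a single digitization per specimen (r=1) the error stratum "
            "is empty and fluctuating asymmetry cannot be separated from "
            "measurement error"
        )
    d_sym = 3 * p + 2 * u - 4
    d_asym = 3 * p + u - 3
    return ((n - 1) * d_sym, d_asym, (n - 1) * d_asym, (r - 1) * n * (d_sym + d_asym))


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    df: int
    ss: float
    ms: float
    f: float | None
    p: float | None
    pct_var: float

    def __post_init__(self) -> None:
        if self.df > 0 and not math.isclose(self.ms * self.df, self.ss, rel_tol=1e-9,
                                            abs_tol=1e-12):
            raise ValueError(f"{self.name}: ms * df != ss")


@dataclass(frozen=True)
class ProcrustesAnovaTable:
    """The four-effect Procrustes ANOVA with the design it was computed under."""

    effects: tuple[AnovaEffect, AnovaEffect, AnovaEffect, AnovaEffect]
    design: tuple[int, int, int, int, int]  # (n, r, p, u, dimension)

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Effect": EFFECT_LABELS[e.name],
                    "df": e.df,
                    "SS": e.ss,
                    "MS": e.ms,
                    "F": e.f,
                    "p": e.p,
                    "% var": e.pct_var,
                }
                for e in self.effects
            ]
        )


def percent_variation(ss_values) -> np.ndarray:
    """Percent of total variation per effect: ``100 * SS / sum(SS)``.

    Follows the convention of reporting SS shares (which is what published
    object-symmetry ANOVA tables print), not mean-square shares.
    """
    ss = np.asarray(ss_values, dtype=float)
    total = ss.sum()
    if total <= 0:
        raise ValueError("total SS must be positive")
    return 100.0 * ss / total


def procrustes_anova(decomp: SymmetryDecomposition) -> ProcrustesAnovaTable:
    """Two-factor Procrustes ANOVA of a symmetry decomposition.

    Requires replicate digitizations (``r >= 2``).  F ratios: individual and
    side over the interaction mean square; interaction over error.
    """
    n, r = decomp.n, decomp.r
    scheme = decomp.scheme
    dfs = anova_dfs(n, r, scheme.n_pairs, scheme.n_midline)

    sids = np.array([sid for sid, _ in decomp.keys])
    order = decomp.specimen_ids
    sym_means = np.stack([decomp.symmetric[sids == sid].mean(axis=0) for sid in order])
    asym_means = np.stack([decomp.asymmetric[sids == sid].mean(axis=0) for sid in order])
    da = decomp.da_vector

    ss_ind = r * float((sym_means**2).sum())
    ss_side = n * r * float((da**2).sum())
    ss_int = r * float(((asym_means - da) ** 2).sum())
    ss_err = 0.0
    for i, sid in enumerate(order):
        mask = sids == sid
        ss_err += float(((decomp.symmetric[mask] - sym_means[i]) ** 2).sum())
        ss_err += float(((decomp.asymmetric[mask] - asym_means[i]) ** 2).sum())
    ss = np.array([ss_ind, ss_side, ss_int, ss_err])

    degenerate = ss.sum() <= 1e-30
    if degenerate:
        logger.warning("degenerate decomposition: all observations identical")
        pct = np.full(4, np.nan)
    else:
        pct = percent_variation(ss)

    ms = ss / np.array(dfs, dtype=float)
    f_num = {"individual": 0, "side": 1, "individual_x_side": 2}
    f_den = {"individual": 2, "side": 2, "individual_x_side": 3}
    effects = []
    for i, name in enumerate(EFFECT_ORDER):
        if name == "error" or degenerate:
            f_val, p_val = None, None
        else:
            num, den = f_num[name], f_den[name]
            if ms[den] > 0:
                f_val = float(ms[num] / ms[den])
                p_val = float(stats.f.sf(f_val, dfs[num], dfs[den]))
            else:
                f_val, p_val = None, None
        effects.append(
            AnovaEffect(
                name=name,
                df=dfs[i],
                ss=float(ss[i]),
                ms=float(ms[i]),
                f=f_val,
                p=p_val,
                pct_var=float(pct[i]),
            )
        )
    return ProcrustesAnovaTable(
        effects=tuple(effects),
        design=(n, r, scheme.n_pairs, scheme.n_midline, 3),
    )
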