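"""Object-symmetry Procrustes superimposition and asymmetry decomposition.

The analysis of a bilaterally symmetric structure ("object symmetry")
proceeds by:

1. building, for every digitized configuration, its *reflected and
   relabelled* copy (one coordinate axis negated, paired landmark rows
   swapped);
2. a generalized Procrustes analysis (GPA) of the joint set of originals and
   mirrors — translate to a common centroid, scale to unit centroid size,
   and iteratively rotate to the evolving consensus by least squares.  The
   consensus of the joint set is symmetric by construction;
3. splitting every observation into a *symmetric component* (the average of
   the aligned original and its aligned mirror, relative to the consensus)
   and an *asymmetric component* (half their difference).  The mean
   asymmetric component over observations is the directional asymmetry (DA)
   of the sample; what remains per individual, after removing DA, is its
   fluctuating asymmetry (FA).

The per-individual *Procrustes FA score* is the Procrustes distance (plain
Euclidean norm in the aligned coordinate space) between the individual's
replicate-averaged asymmetric component and the DA vector.

The entry point is :class:`ObjectSymmetryModel`, whose :meth:`fit` returns
an :class:`ObjectSymmetryResults` carrying the consensus, the aligned
shapes, the decomposition, FA scores and the Procrustes ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, LandmarkConfiguration
from .scheme import LandmarkScheme

logger = logging.getLogger(__name__)

_REFLECT = np.array([-1.0, 1.0, 1.0])


class GPAError(RuntimeError):
    pass


def reflect_relabel(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Reflect a configuration (negate x) and swap each bilateral pair's rows.

    This is the relabelled mirror image used throughout object-symmetry
    analysis; it is an involution.  Which plane the raw data are reflected
    through is irrelevant downstream because superimposition removes
    orientation — the mirror only needs to be *a* reflection.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (scheme.n_landmarks, 3):
        raise ValueError(
            f"expected {(scheme.n_landmarks, 3)} coordinates, got {coords.shape}"
        )
    return (coords * _REFLECT)[scheme.relabel_permutation()]


def reflect_relabel_config(
    config: LandmarkConfiguration, scheme: LandmarkScheme
) -> LandmarkConfiguration:
    return LandmarkConfiguration(
        config.specimen_id, config.replicate_id, reflect_relabel(config.coords, scheme)
    )


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid."""
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center_and_scale(coords: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and scale to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs < 1e-12:
        raise GPAError("degenerate configuration with zero centroid size")
    return centered / cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation Q (det +1) minimising ||source @ Q - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class AlignedShape:
    """One superimposed observation (centroid at origin, unit centroid size)."""

    specimen_id: str
    replicate_id: int
    is_mirror: bool
    coords: np.ndarray

    @property
    def key(self) -> tuple[str, int]:
        return (self.specimen_id, self.replicate_id)


def _canonical_symmetric(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Rotate a centered shape so its best mirror plane is x=0, then symmetrize.

    The rotation sends the axis along which the shape is *least* congruent
    with its relabelled mirror to x; averaging with the reflected-relabelled
    copy in that frame then yields an exactly reflection-invariant shape.
    """
    perm = scheme.relabel_permutation()
    m = coords.T @ coords[perm]
    m_s = 0.5 * (m + m.T)
    eigvals, eigvecs = np.linalg.eigh(m_s)
    q1 = eigvecs[:, 0]  # smallest eigenvalue -> mirror-mismatch axis
    if q1[0] < 0:
        q1 = -q1
    # complete to the right-handed orthonormal basis closest to the identity,
    # so a shape already in mirror-canonical orientation is left (nearly) fixed
    helper = np.eye(3)[np.argmin(np.abs(q1[[1, 2]])) + 1]
    q2 = helper - q1 * (q1 @ helper)
    q2 /= np.linalg.norm(q2)
    q3 = np.cross(q1, q2)
    q = np.column_stack([q1, q2, q3])
    rotated = coords @ q
    sym = 0.5 * (rotated + reflect_relabel(rotated, scheme))
    return center_and_scale(sym)


def gpa(
    observations: list[AlignedShape] | list[np.ndarray],
    scheme: LandmarkScheme,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, list[AlignedShape]]:
    """Generalized Procrustes fit of a set already containing mirrors.

    Every observation is centered, scaled to unit centroid size and
    iteratively rotated (proper rotations only — reflection enters solely
    through the explicit relabelled mirrors) to the consensus.  The consensus
    is re-estimated as the mean shape, re-scaled to unit size and kept
    exactly reflection-invariant; iteration stops when its RMS change falls
    below ``tol``.
    """
    if not observations:
        raise GPAError("no observations")
    if isinstance(observations[0], np.ndarray):
        observations = [
            AlignedShape("obs", i + 1, False, c) for i, c in enumerate(observations)
        ]
    mats = [center_and_scale(o.coords) for o in observations]
    consensus = _canonical_symmetric(mats[0], scheme)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = [x @ optimal_rotation(x, consensus) for x in mats]
        new = np.mean(aligned, axis=0)
        new = center_and_scale(new)
        new = 0.5 * (new + reflect_relabel(new, scheme))
        new = center_and_scale(new)
        change = np.sqrt(np.mean((new - consensus) ** 2))
        consensus = new
        if change < tol:
            break
    logger.info("GPA converged in %d iterations", n_iter)
    aligned_shapes = [
        AlignedShape(o.specimen_id, o.replicate_id, o.is_mirror, x @ optimal_rotation(x, consensus))
        for o, x in zip(observations, mats)
    ]
    return consensus, aligned_shapes


@dataclass(frozen=True)
class SymmetryDecomposition:
    """Aligned observations split into symmetric and asymmetric components.

    Components are tangent-space deviations from the consensus, one row set
    per *original* (non-mirror) observation, in the sorted (specimen,
    replicate) order of ``keys``.  ``da_vector`` is the mean asymmetric
    component — the directional asymmetry of the sample.
    """

    consensus: np.ndarray
    keys: tuple[tuple[str, int], ...]
    symmetric: np.ndarray  # (n*r, k, 3)
    asymmetric: np.ndarray  # (n*r, k, 3)
    da_vector: np.ndarray  # (k, 3)
    scheme: LandmarkScheme
    n: int
    r: int

    @property
    def specimen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.keys:
            seen.setdefault(sid)
        return list(seen)


def decompose(
    aligned: list[AlignedShape],
    consensus: np.ndarray,
    scheme: LandmarkScheme,
) -> SymmetryDecomposition:
    """Split aligned original/mirror couples into symmetric + asymmetric parts.

    For each (specimen, replicate) couple with aligned original ``X`` and
    aligned mirror ``M``: ``symmetric = (X + M)/2 - consensus`` and
    ``asymmetric = (X - M)/2``; their sum is the observation's total
    deviation from the consensus, and the two parts are orthogonal.
    """
    originals = {o.key: o for o in aligned if not o.is_mirror}
    mirrors = {o.key: o for o in aligned if o.is_mirror}
    missing = sorted(set(originals) ^ set(mirrors))
    if missing:
        raise GPAError(f"observations without a mirror partner: {missing}")
    keys = sorted(originals)
    sym = np.empty((len(keys),) + consensus.shape)
    asym = np.empty_like(sym)
    for i, key in enumerate(keys):
        x, m = originals[key].coords, mirrors[key].coords
        sym[i] = 0.5 * (x + m) - consensus
        asym[i] = 0.5 * (x - m)
    counts: dict[str, int] = {}
    for sid, _ in keys:
        counts[sid] = counts.get(sid, 0) + 1
    r_values = set(counts.values())
    if len(r_values) != 1:
        raise GPAError(f"unequal replicate counts: {counts}")
    return SymmetryDecomposition(
        consensus=consensus,
        keys=tuple(keys),
        symmetric=sym,
        asymmetric=asym,
        da_vector=asym.mean(axis=0),
        scheme=scheme,
        n=len(counts),
        r=r_values.pop(),
    )


def fa_scores(decomp: SymmetryDecomposition) -> pd.DataFrame:
    """Per-individual Procrustes FA scores.

    Each individual's replicate-averaged asymmetric component, minus the
    sample directional asymmetry, measured as a Procrustes distance
    (Frobenius norm in the aligned space).  ``da_projection`` is the signed
    projection of the individual's mean asymmetry onto the DA direction.
    """
    sids = np.array([sid for sid, _ in decomp.keys])
    rows = []
    da = decomp.da_vector
    da_norm = np.linalg.norm(da)
    for sid in decomp.specimen_ids:
        mean_asym = decomp.asymmetric[sids == sid].mean(axis=0)
        score = float(np.linalg.norm(mean_asym - da))
        proj = float((mean_asym * da).sum() / da_norm) if da_norm > 0 else np.nan
        rows.append({"specimen_id": sid, "fa_score": score, "da_projection": proj})
    return pd.DataFrame(rows)


def summarize_fa_scores(scores: pd.DataFrame | pd.Series) -> dict[str, float]:
    """Mean / median / SD of a table of Procrustes FA scores."""
    s = scores["fa_score"] if isinstance(scores, pd.DataFrame) else scores
    s = pd.to_numeric(s, errors="raise")
    return {
        "mean": float(s.mean()),
        "median": float(s.median()),
        "sd": float(s.std(ddof=1)),
    }


def load_fa_score_table(path, column: str = "fa_score") -> pd.DataFrame:
    """Read a deposited per-individual FA score table (CSV).

    Accepts any CSV with a column of Procrustes FA scores (named ``fa_score``
    or the first numeric column found); returns a normalised two-column
    table.  Intended for externally supplied score tables such as a study's
    supplementary data.
    """
    df = pd.read_csv(path)
    if column not in df.columns:
        numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        if not numeric:
            raise ValueError(f"{path}: no numeric FA score column found")
        column = numeric[-1]
    ids = df.columns[0]
    out = pd.DataFrame(
        {"specimen_id": df[ids].astype(str), "fa_score": pd.to_numeric(df[column])}
    )
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ObjectSymmetryModel:
    """Object-symmetry Procrustes model for a replicated landmark dataset.

    Parameters
    ----------
    dataset
        Validated :class:`~fasym.io.Dataset` (n individuals x r replicates).

    ``fit()`` mirrors the usual estimator idiom: it performs the joint GPA of
    all ``2 n r`` observations (originals plus relabelled mirrors), the
    symmetric/asymmetric decomposition, and returns an
    :class:`ObjectSymmetryResults`.
    """

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self.scheme = dataset.scheme

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> "ObjectSymmetryResults":
        observations: list[AlignedShape] = []
        for config in self.dataset.configurations:
            observations.append(
                AlignedShape(config.specimen_id, config.replicate_id, False, config.coords)
            )
            observations.append(
                AlignedShape(
                    config.specimen_id,
                    config.replicate_id,
                    True,
                    reflect_relabel(config.coords, self.scheme),
                )
            )
        consensus, aligned = gpa(observations, self.scheme, tol=tol, max_iter=max_iter)
        decomp = decompose(aligned, consensus, self.scheme)
        return ObjectSymmetryResults(self, consensus, aligned, decomp)


class ObjectSymmetryResults:
    """Fitted object-symmetry superimposition and asymmetry decomposition."""

    def __init__(
        self,
        model: ObjectSymmetryModel,
        consensus: np.ndarray,
        aligned: list[AlignedShape],
        decomposition: SymmetryDecomposition,
    ):
        self.model = model
        self.consensus = consensus
        self.aligned = aligned
        self.decomposition = decomposition

    @property
    def da_vector(self) -> np.ndarray:
        return self.decomposition.da_vector

    def fa_scores(self) -> pd.DataFrame:
        return fa_scores(self.decomposition)

    def anova(self):
        from .anova import procrustes_anova

        return procrustes_anova(self.decomposition)

    def summary(self) -> str:
        d = self.decomposition
        table = self.anova()
        scores = self.fa_scores()["fa_score"]
        lines = [
            "Object-symmetry Procrustes analysis",
            "===================================",
            f"individuals: {d.n}   replicates: {d.r}   "
            f"landmarks: {d.scheme.n_landmarks} "
            f"({d.scheme.n_pairs} pairs + {d.scheme.n_midline} midline)",
            f"directional asymmetry magnitude: {np.linalg.norm(d.da_vector):.6f}",
            f"Procrustes FA scores: mean {scores.mean():.4f}, "
            f"median {scores.median():.4f}, SD {scores.std(ddof=1):.4f}",
            "",
            table.to_dataframe().to_string(index=False),
        ]
        return "\n".join(lines)
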