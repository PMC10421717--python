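"""Synthetic landmark datasets with controlled asymmetry structure.

The generator mirrors the statistical structure that the object-symmetry
analysis assumes, so every pipeline stage can be exercised without real
crania:

* a symmetric template shape (bilateral pairs mirrored across ``x = 0``,
  midline landmarks on ``x = 0``);
* per-individual deviations drawn in the *symmetric* subspace (shared by the
  two sides) with SD ``sigma_sym``;
* a fixed *directional asymmetry* field of norm ``da_magnitude`` shared by
  all individuals;
* per-individual deviations in the *asymmetric* subspace (fluctuating
  asymmetry) with SD ``sigma_fa``, optionally inflated by a factor
  ``kappa_g`` in chosen exposure groups;
* per-replicate, per-coordinate digitizing noise with SD ``sigma_err``;
* an arbitrary rigid motion plus positive scaling applied independently to
  every configuration (which superimposition must remove).

Subspace conventions (reflection = negate x, swap paired rows): a symmetric
deviation moves a left landmark by ``(a, b, c)`` and its right partner by
``(-a, b, c)`` and midline landmarks by ``(0, b, c)``; an asymmetric
deviation moves left by ``(a, b, c)``, right by ``(a, -b, -c)`` and midline
by ``(a, 0, 0)``.  The two subspaces are orthogonal complements of the
centered coordinate space.

Default magnitudes are a calibration, not measurements: they are chosen so
that the default cohort reproduces the variance shares typical of replicate
cranial digitizing studies (individual variation ~91%, directional asymmetry
well under 1%, fluctuating asymmetry a few percent, measurement error ~5%)
and a mean Procrustes FA score of ~0.015.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Dataset, LandmarkConfiguration, validate_metadata
from .scheme import LandmarkScheme

# Hurricane landfall years on the island the cohort structure mimics.
HURRICANE_YEARS = (1989, 1998)

# Skeletal maturity thresholds (years): males mature at 8, females at 15.
MATURITY = {"M": 8.0, "F": 15.0}


@dataclass(frozen=True)
class ExposureDesign:
    """Group sizes and per-group fluctuating-asymmetry inflation factors.

    The default mirrors the study cohort: 174 never-exposed individuals and
    101 exposed (10 as fetuses, 50 as juveniles, 41 as adults), of whom 78
    experienced one hurricane and 23 experienced two.  ``kappa`` multiplies
    ``sigma_fa`` for the group; the default inflates the fetal group by 1.4,
    the minimal mechanism consistent with a fetal-exposure elevation of FA.
    """

    n_never: int = 174
    n_fetal: int = 10
    n_juvenile: int = 50
    n_adult: int = 41
    n_two_hurricanes: int = 23
    kappa: dict = field(
        default_factory=lambda: {
            "none": 1.0, "fetal": 1.4, "juvenile": 1.0, "adult": 1.0,
        }
    )

    @property
    def n_total(self) -> int:
        return self.n_never + self.n_fetal + self.n_juvenile + self.n_adult

    @property
    def n_exposed(self) -> int:
        return self.n_fetal + self.n_juvenile + self.n_adult

    def scaled(self, n: int) -> "ExposureDesign":
        """Proportionally rescale group sizes to a cohort of ``n`` individuals."""
        if n == self.n_total:
            return self
        frac = n / self.n_total
        sizes = {
            k: max(1, round(getattr(self, k) * frac))
            for k in ("n_fetal", "n_juvenile", "n_adult", "n_two_hurricanes")
        }
        sizes["n_never"] = n - sizes["n_fetal"] - sizes["n_juvenile"] - sizes["n_adult"]
        if sizes["n_never"] < 0:
            raise ValueError(f"cannot scale exposure design down to n={n}")
        sizes["n_two_hurricanes"] = min(sizes["n_two_hurricanes"], sizes["n_fetal"]
                                        + sizes["n_juvenile"] + sizes["n_adult"])
        return replace(self, kappa=dict(self.kappa), **sizes)


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterisation of the landmark-level generator.

    SDs are in the same units as the template coordinates (nominally mm;
    superimposition removes scale, so only ratios to the template centroid
    size matter).  The defaults describe the emulated study: n=275
    individuals digitized twice, 13 bilateral pairs + 8 midline landmarks.
    """

    n: int = 275
    r: int = 2
    p: int = 13
    u: int = 8
    sigma_sym: float = 0.80
    da_magnitude: float = 0.45
    sigma_fa: float = 0.096
    sigma_err: float = 0.26
    exposure: ExposureDesign = field(default_factory=ExposureDesign)
    n_matrilines: int = 30
    template_size: float = 100.0
    geometry_seed: int = 7
    seed: int = 0
    apply_nuisance: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma_sym", "da_magnitude", "sigma_fa", "sigma_err"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(k <= 0 for k in self.exposure.kappa.values()):
            raise ValueError("exposure inflation factors must be > 0")
        if self.n < 1 or self.r < 1 or self.p < 1 or self.u < 0:
            raise ValueError("invalid design sizes")

    @property
    def scheme(self) -> LandmarkScheme:
        p, u = self.p, self.u
        pairs = tuple((2 * i, 2 * i + 1) for i in range(p))
        midline = tuple(range(2 * p, 2 * p + u))
        return LandmarkScheme(n_landmarks=2 * p + u, pairs=pairs, midline=midline)


def make_template(
    p: int, u: int, geometry_seed: int = 7, size: float = 100.0
) -> np.ndarray:
    """Draw a non-degenerate symmetric base shape of ``2p + u`` 3-D points.

    Pair members are exact mirror images across ``x = 0`` (left member at
    ``x > 0``), midline points sit on ``x = 0``; the shape is centered and
    scaled to centroid size ``size``.
    """
    if p < 1:
        raise ValueError("need at least one bilateral pair")
    rng = np.random.default_rng(geometry_seed)
    k = 2 * p + u
    for _ in range(100):
        coords = np.empty((k, 3))
        left = np.column_stack(
            [rng.uniform(0.3, 1.0, p), rng.uniform(-1, 1, p), rng.uniform(-1, 1, p)]
        )
        coords[0 : 2 * p : 2] = left
        coords[1 : 2 * p : 2] = left * np.array([-1.0, 1.0, 1.0])
        if u:
            coords[2 * p :] = np.column_stack(
                [np.zeros(u), rng.uniform(-1, 1, u), rng.uniform(-1, 1, u)]
            )
        centered = coords - coords.mean(axis=0)
        # midline x-coords stay exactly 0: the centroid has x = 0 by mirror symmetry
        cs = math.sqrt((centered**2).sum())
        if cs < 1e-9:
            continue
        centered *= size / cs
        if np.linalg.matrix_rank(centered, tol=1e-6) == 3 and _min_dist(centered) > 1e-3:
            return centered
    raise RuntimeError("failed to draw a non-degenerate template")


def _min_dist(x: np.ndarray) -> float:
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def symmetric_deviation(rng: np.random.Generator, p: int, u: int, sigma: float) -> np.ndarray:
    """Random deviation in the symmetric subspace, i.i.d. N(0, sigma^2) components."""
    dev = np.zeros((2 * p + u, 3))
    abc = rng.normal(0.0, sigma, size=(p, 3))
    dev[0 : 2 * p : 2] = abc
    dev[1 : 2 * p : 2] = abc * np.array([-1.0, 1.0, 1.0])
    if u:
        dev[2 * p :, 1:] = rng.normal(0.0, sigma, size=(u, 2))
    return dev


def asymmetric_deviation(rng: np.random.Generator, p: int, u: int, sigma: float) -> np.ndarray:
    """Random deviation in the asymmetric subspace, i.i.d. N(0, sigma^2) components."""
    dev = np.zeros((2 * p + u, 3))
    abc = rng.normal(0.0, sigma, size=(p, 3))
    dev[0 : 2 * p : 2] = abc
    dev[1 : 2 * p : 2] = abc * np.array([1.0, -1.0, -1.0])
    if u:
        dev[2 * p :, 0] = rng.normal(0.0, sigma, size=u)
    return dev


def directional_asymmetry_field(
    p: int, u: int, magnitude: float, seed: int = 13
) -> np.ndarray:
    """Fixed asymmetric-subspace field with Frobenius norm ``magnitude``."""
    if magnitude == 0:
        return np.zeros((2 * p + u, 3))
    rng = np.random.default_rng(seed)
    v = asymmetric_deviation(rng, p, u, 1.0)
    return v * (magnitude / np.linalg.norm(v))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed to +1)."""
    q, rmat = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(rmat))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def nuisance_transform(
    coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Apply a random similarity transform (rotation, translation, scaling)."""
    rot = random_rotation(rng)
    scale = float(np.exp(rng.uniform(-0.2, 0.2)))
    translation = rng.uniform(-50.0, 50.0, size=3)
    return scale * coords @ rot + translation


def similarity_tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions at a template shape.

    The seven tangent directions that superimposition removes: three
    translations, three infinitesimal rotations (generator fields ``G @ x``)
    and the scale direction (the centered template itself).  Returned as an
    orthonormal ``(7, k, 3)`` stack (Frobenius inner product).
    """
    centered = template - template.mean(axis=0)
    k = centered.shape[0]
    fields = []
    for axis in range(3):
        t = np.zeros((k, 3))
        t[:, axis] = 1.0
        fields.append(t)
    gens = (
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),  # about x
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),  # about y
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),  # about z
    )
    fields.extend(centered @ g.T for g in gens)
    fields.append(centered)
    flat = np.stack([f.ravel() for f in fields])
    q, _ = np.linalg.qr(flat.T)
    return q.T.reshape(-1, k, 3)


def project_out_similarity(deviation: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Remove the components of a deviation field along the similarity directions.

    Deviations built this way survive superimposition unchanged (to second
    order in their magnitude), which makes exact component-recovery tests
    possible.
    """
    basis = similarity_tangent_basis(template)
    dev = deviation.copy()
    for b in basis:
        dev -= (dev * b).sum() * b
    return dev


# ---------------------------------------------------------------------------
# Metadata generation
# ---------------------------------------------------------------------------

def simulate_metadata(
    n: int,
    exposure: ExposureDesign | None = None,
    n_matrilines: int = 30,
    seed: int = 0,
    female_fraction: float = 154 / 275,
) -> pd.DataFrame:
    """Generate a specimen-metadata table with the emulated cohort structure.

    Sexes split ~154 F : 121 M; birth years span 1951-2005; exposure classes
    are assigned per the design and ages are drawn so that the skeletal
    maturity rule (males mature at 8 yr, females at 15 yr) is respected for
    the juvenile/adult-at-hurricane classification.
    """
    exposure = (exposure or ExposureDesign()).scaled(n)
    rng = np.random.default_rng(seed)
    n_f = round(n * female_fraction)
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)

    classes = (
        ["none"] * exposure.n_never
        + ["fetal"] * exposure.n_fetal
        + ["juvenile"] * exposure.n_juvenile
        + ["adult"] * exposure.n_adult
    )
    rows = []
    exposed_idx = [i for i, c in enumerate(classes) if c != "none"]
    two_set = set(
        rng.choice(exposed_idx, size=min(exposure.n_two_hurricanes, len(exposed_idx)),
                   replace=False)
    ) if exposed_idx else set()
    for i, cls in enumerate(classes):
        sex = sexes[i]
        maturity = MATURITY[sex]
        if cls == "none":
            n_hur = 0
            # never exposed: born after the last hurricane, or died before the first
            if rng.random() < 0.7:
                birth = rng.uniform(HURRICANE_YEARS[-1] + 0.1, 2005.0)
                age_death = rng.uniform(0.75, min(31.0, 2012.0 - birth))
            else:
                birth = rng.uniform(1951.0, 1984.0)
                age_death = rng.uniform(0.75, min(31.0, HURRICANE_YEARS[0] - birth - 0.1))
        else:
            n_hur = 2 if i in two_set else 1
            hyear = HURRICANE_YEARS[0] if n_hur == 2 else HURRICANE_YEARS[rng.integers(2)]
            if cls == "fetal":
                age_at_h = 0.0
            elif cls == "juvenile":
                age_at_h = rng.uniform(0.75, maturity - 0.25)
            else:
                age_at_h = rng.uniform(maturity + 0.25, maturity + 12.0)
            birth = hyear - age_at_h
            age_death = min(31.0, age_at_h + rng.uniform(0.75, 18.0))
        rows.append(
            {
                "specimen_id": f"S{i + 1:04d}",
                "sex": sex,
                "age_at_death": round(float(age_death), 2),
                "decade_of_birth": int(birth // 10) * 10,
                "matriline": f"mat{rng.integers(n_matrilines) + 1:02d}",
                "n_hurricanes": n_hur,
                "age_at_hurricane": cls,
            }
        )
    return validate_metadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Landmark-level generator
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimulationParams | None = None, **overrides) -> Dataset:
    """Generate a full landmark :class:`Dataset` under ``params``.

    Deterministic for a given parameter set (all randomness flows from
    ``params.seed`` through independent child streams for metadata, shape
    deviations and nuisance transforms).
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    scheme = params.scheme
    p, u = params.p, params.u
    template = make_template(p, u, params.geometry_seed, params.template_size)
    da_field = directional_asymmetry_field(p, u, params.da_magnitude)

    root = np.random.SeedSequence(params.seed)
    meta_seed, shape_seed, noise_seed, nuisance_seed = root.spawn(4)
    metadata = simulate_metadata(
        params.n, params.exposure, params.n_matrilines,
        seed=meta_seed, female_fraction=154 / 275,
    )
    shape_rng = np.random.default_rng(shape_seed)
    noise_rng = np.random.default_rng(noise_seed)
    nuis_rng = np.random.default_rng(nuisance_seed)

    kappa = params.exposure.kappa
    configs: list[LandmarkConfiguration] = []
    for row in metadata.itertuples(index=False):
        k_g = kappa.get(row.age_at_hurricane, 1.0)
        sym_dev = symmetric_deviation(shape_rng, p, u, params.sigma_sym)
        asym_dev = asymmetric_deviation(shape_rng, p, u, params.sigma_fa * k_g)
        true_shape = template + sym_dev + asym_dev + da_field
        for rep in range(1, params.r + 1):
            coords = true_shape + noise_rng.normal(
                0.0, params.sigma_err, size=true_shape.shape
            )
            if params.apply_nuisance:
                coords = nuisance_transform(coords, nuis_rng)
            configs.append(LandmarkConfiguration(row.specimen_id, rep, coords))
    return Dataset(scheme=scheme, configurations=tuple(configs), metadata=metadata)


# ---------------------------------------------------------------------------
# Score-level generator (for fast mixed-model tests)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreParams:
    """Direct generator for per-individual FA scores over a metadata table.

    ``score = intercept + X beta + matriline intercept + residual``, with the
    same metadata schema the landmark path produces.  ``beta`` maps covariate
    names to score-level effects: continuous ``age`` (years) and
    ``decade_index`` (decades since 1950), and additive group offsets
    ``male``, ``hurricane``, ``one_hurricane``, ``two_hurricanes``,
    ``juvenile``, ``adult`` (the last two relative to fetal exposure).
    """

    n: int = 275
    intercept: float = 0.015
    beta: dict = field(default_factory=dict)
    sigma_matriline: float = 0.001
    sigma_residual: float = 0.004
    exposure: ExposureDesign = field(default_factory=ExposureDesign)
    n_matrilines: int = 30
    seed: int = 0


def simulate_scores(params: ScoreParams | None = None, **overrides) -> pd.DataFrame:
    """Generate a joined FA-score + metadata table from score-level components."""
    if params is None:
        params = ScoreParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    root = np.random.SeedSequence(params.seed)
    meta_seed, score_seed = root.spawn(2)
    md = simulate_metadata(
        params.n, params.exposure, params.n_matrilines, seed=meta_seed
    )
    rng = np.random.default_rng(score_seed)
    b = params.beta
    mu = np.full(len(md), params.intercept)
    mu += b.get("age", 0.0) * md["age_at_death"].to_numpy()
    mu += b.get("decade_index", 0.0) * (md["decade_of_birth"].to_numpy() - 1950) / 10
    mu += b.get("male", 0.0) * (md["sex"] == "M").to_numpy()
    mu += b.get("hurricane", 0.0) * md["hurricane_experienced"].to_numpy()
    mu += b.get("one_hurricane", 0.0) * (md["n_hurricanes"] == 1).to_numpy()
    mu += b.get("two_hurricanes", 0.0) * (md["n_hurricanes"] == 2).to_numpy()
    mu += b.get("juvenile", 0.0) * (md["age_at_hurricane"] == "juvenile").to_numpy()
    mu += b.get("adult", 0.0) * (md["age_at_hurricane"] == "adult").to_numpy()
    mats = sorted(md["matriline"].unique())
    offsets = dict(zip(mats, rng.normal(0.0, params.sigma_matriline, len(mats))))
    scores = (
        mu
        + md["matriline"].map(offsets).to_numpy()
        + rng.normal(0.0, params.sigma_residual, len(md))
    )
    out = md.copy()
    out.insert(1, "fa_score", scores)
    return out
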