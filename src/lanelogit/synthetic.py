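"""Seeded synthetic cyclist-behavior datasets with known ground truth.

The field data behind the motivating study were never released, so every
stage of the pipeline is exercised on simulated data whose generating model
is known exactly.  The generator reproduces the study's covariate structure:
fourteen categorical variables with the observed marginal frequencies, an
optional site-block mode in which road-geometry variables are inherited from
one of the eight surveyed sites, and binary outcomes drawn from a
random-parameter logit — each rider i receives a coefficient vector
``beta_i ~ N(mu, diag(sigma^2))`` and occupies the motor lane with
probability ``expit(beta_i . x_i)``.  Realized coefficients are stored so
recovery tests can compare against them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ObservationSet
from .encoding import DEFAULT_REFERENCES, DesignMatrix, ReferenceMap, build_design_matrix
from .reference import CATEGORY_COUNTS

__all__ = [
    "FacilityProfile",
    "CovariateScheme",
    "TrueModel",
    "SyntheticDataset",
    "DEFAULT_SITES",
    "default_scheme",
    "sample_covariates",
    "simulate_outcomes",
    "write_dataset",
    "read_dataset",
]

#: Variables tied to the road segment rather than the individual rider; in
#: site-block mode these are inherited from a sampled FacilityProfile.
GEOMETRY_VARIABLES = ("dividing_strip", "bike_lane_width", "vehicle_lanes", "on_street_parking")


@dataclass(frozen=True)
class FacilityProfile:
    """Road geometry of one survey site."""

    facility_id: str
    dividing_strip: str
    bike_lane_width: str
    vehicle_lanes: str
    on_street_parking: str  # "yes"/"no"

    _STRIPS = ("greenbelt", "barriers", "marking", "pedestrian_bicycle", "mixed")
    _WIDTHS = ("1.5", "2.5", "3.5", "4.5")
    _LANES = ("1", "2", "3", "4")

    def __post_init__(self) -> None:
        if self.dividing_strip not in self._STRIPS:
            raise ValueError(f"unknown dividing strip {self.dividing_strip!r}")
        if self.bike_lane_width not in self._WIDTHS:
            raise ValueError(f"unknown bike-lane width class {self.bike_lane_width!r}")
        if self.vehicle_lanes not in self._LANES:
            raise ValueError(f"unknown vehicle-lane count {self.vehicle_lanes!r}")
        if self.on_street_parking not in ("yes", "no"):
            raise ValueError("on_street_parking must be 'yes' or 'no'")


#: The eight surveyed road segments (geometry as reported by the field study).
DEFAULT_SITES: tuple[FacilityProfile, ...] = (
    FacilityProfile("jianshe", "greenbelt", "4.5", "4", "no"),
    FacilityProfile("guangming", "greenbelt", "3.5", "2", "yes"),
    FacilityProfile("kaiyuan_n", "marking", "2.5", "2", "yes"),
    FacilityProfile("kaiyuan_s", "barriers", "2.5", "2", "no"),
    FacilityProfile("kuanggong", "marking", "2.5", "3", "no"),
    FacilityProfile("lingyun", "barriers", "2.5", "3", "no"),
    FacilityProfile("zhanbei", "pedestrian_bicycle", "2.5", "1", "no"),
    FacilityProfile("shuguang", "mixed", "1.5", "1", "yes"),
)


def _validate_probs(var: str, cats: tuple[str, ...], probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(cats):
        raise ValueError(f"variable {var!r}: {len(cats)} categories but {len(probs)} probabilities")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"variable {var!r}: probabilities must be non-negative and sum to 1")
    return probs


@dataclass(frozen=True)
class CovariateScheme:
    """Per-variable category lists with sampling probabilities.

    ``site_block=True`` ties the road-geometry variables to a sampled site
    profile (reflecting that in field data those covariates are perfectly
    nested within sites); otherwise all variables are sampled independently.
    """

    categories: dict[str, tuple[str, ...]]
    probabilities: dict[str, np.ndarray]
    site_block: bool = False
    sites: tuple[FacilityProfile, ...] = DEFAULT_SITES
    site_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        for var, cats in self.categories.items():
            object.__setattr__(
                self,
                "probabilities",
                {**self.probabilities, var: _validate_probs(var, cats, self.probabilities[var])},
            )
        if self.site_block:
            if not self.sites:
                raise ValueError("site_block mode requires at least one site")
            ids = [s.facility_id for s in self.sites]
            if len(set(ids)) != len(ids):
                raise ValueError("facility_id must be unique within a scheme")
            w = self.site_weights
            if w is not None:
                object.__setattr__(self, "site_weights", _validate_probs("sites", ids, w))

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.categories)


def default_scheme(site_block: bool = False) -> CovariateScheme:
    """Scheme with the field study's observed marginal frequencies.

    Probabilities are the exact observed counts divided by 34,631 (the
    published percentages are these values rounded).  In site-block mode the
    eight surveyed sites are weighted so that dividing-strip marginals are
    preserved, splitting each strip's frequency evenly across its sites.
    """
    categories = {v: tuple(c) for v, c in CATEGORY_COUNTS.items()}
    probabilities = {
        v: np.array(list(c.values()), dtype=float) / sum(c.values())
        for v, c in CATEGORY_COUNTS.items()
    }
    weights = None
    if site_block:
        strip_counts = CATEGORY_COUNTS["dividing_strip"]
        per_strip = {
            s: sum(1 for p in DEFAULT_SITES if p.dividing_strip == s) for s in strip_counts
        }
        weights = np.array(
            [strip_counts[p.dividing_strip] / per_strip[p.dividing_strip] for p in DEFAULT_SITES],
            dtype=float,
        )
        weights /= weights.sum()
    return CovariateScheme(
        categories=categories,
        probabilities=probabilities,
        site_block=site_block,
        site_weights=weights,
    )


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth random-parameter logit used to simulate outcomes.

    ``mu`` maps design-column labels (``"intercept"`` or
    ``"<variable>:<level> vs <reference>"``) to coefficient means in log-odds
    units; ``sigma`` to coefficient SDs (zero or absent = fixed coefficient).
    """

    mu: dict[str, float]
    sigma: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma for {label!r} must be >= 0")

    def vectors(self, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Align (mu, sigma) onto the given design columns; unknown labels error."""
        unknown = (set(self.mu) | set(self.sigma)) - set(columns)
        if unknown:
            raise ValueError(f"true-model labels not in design matrix: {sorted(unknown)}")
        mu = np.array([self.mu.get(c, 0.0) for c in columns])
        sigma = np.array([self.sigma.get(c, 0.0) for c in columns])
        return mu, sigma

    @property
    def random_labels(self) -> list[str]:
        return [c for c, s in self.sigma.items() if s > 0]


@dataclass
class SyntheticDataset:
    """Simulated observations together with the truth that generated them."""

    observations: ObservationSet
    truth: TrueModel
    design: DesignMatrix
    realized_beta: np.ndarray  # (n, k+1), per-observation coefficients
    p: np.ndarray  # (n,) occupancy probabilities

    @property
    def n(self) -> int:
        return self.observations.n


def _variable_rng(seed: int, name: str) -> np.random.Generator:
    # Stable per-variable stream: adding a variable never perturbs others.
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    return np.random.default_rng(np.random.SeedSequence([seed, int.from_bytes(digest, "big")]))


def sample_covariates(scheme: CovariateScheme, n: int, seed: int) -> ObservationSet:
    """Draw ``n`` rows of categorical covariates under ``scheme``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, np.ndarray] = {}
    site_of_row = None
    if scheme.site_block:
        rng = _variable_rng(seed, "__site__")
        w = scheme.site_weights
        idx = rng.choice(len(scheme.sites), size=n, p=w)
        site_of_row = [scheme.sites[i] for i in idx]
    for var in scheme.variables:
        if site_of_row is not None and var in GEOMETRY_VARIABLES:
            out[var] = np.array([getattr(s, var) for s in site_of_row], dtype=object)
            continue
        rng = _variable_rng(seed, var)
        cats = np.array(scheme.categories[var], dtype=object)
        out[var] = cats[rng.choice(len(cats), size=n, p=scheme.probabilities[var])]
    return ObservationSet(covariates=pd.DataFrame(out))


def simulate_outcomes(
    covariates: ObservationSet,
    truth: TrueModel,
    refs: ReferenceMap = DEFAULT_REFERENCES,
    groups: np.ndarray | None = None,
) -> SyntheticDataset:
    """Draw per-rider coefficients and Bernoulli outcomes under ``truth``.

    With ``groups`` (one label per row) the random coefficients are realised
    once per group and shared by its members — the group-level counterpart
    of the default observation-level heterogeneity.
    """
    dm = build_design_matrix(covariates.covariates, refs)
    mu, sigma = truth.vectors(dm.columns)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x6F7574]))
    if groups is None:
        beta = mu + sigma * rng.standard_normal((dm.n, len(dm.columns)))
    else:
        if len(groups) != dm.n:
            raise ValueError("groups must have one label per row")
        g = np.unique(np.asarray(groups), return_inverse=True)[1]
        beta_g = mu + sigma * rng.standard_normal((int(g.max()) + 1, len(dm.columns)))
        beta = beta_g[g]
    p = expit(np.einsum("ij,ij->i", beta, dm.X))
    y = (rng.random(dm.n) < p).astype(np.int8)
    obs = ObservationSet(covariates=covariates.covariates, y=y)
    return SyntheticDataset(observations=obs, truth=truth, design=dm, realized_beta=beta, p=p)


def write_dataset(ds: SyntheticDataset, path: str | Path) -> Path:
    """Write observations as CSV; the generating truth goes to ``<path>.truth.json``.

    Column order is the outcome first, then covariates in scheme order —
    stable across runs so files diff cleanly.
    """
    if ds.n == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    ds.observations.to_frame().to_csv(path, index=False)
    truth = {
        "mu": ds.truth.mu,
        "sigma": ds.truth.sigma,
        "seed": ds.truth.seed,
        "n": ds.n,
    }
    path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(truth, indent=2))
    return path


def read_dataset(path: str | Path) -> ObservationSet:
    """Read a dataset CSV written by :func:`write_dataset` (or hand-made)."""
    frame = pd.read_csv(path, dtype=str)
    if frame.isna().any().any():
        rows = frame.index[frame.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing values in rows {rows}")
    from .data import OUTCOME_COLUMN

    if OUTCOME_COLUMN in frame.columns:
        vals = frame[OUTCOME_COLUMN]
        bad = ~vals.isin(["0", "1"])
        if bad.any():
            raise ValueError(
                f"outcome column must be 0/1; offending rows: {frame.index[bad][:5].tolist()}"
            )
        frame[OUTCOME_COLUMN] = vals.astype(int)
    return ObservationSet.from_frame(frame)
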