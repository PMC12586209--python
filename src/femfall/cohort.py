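"""Synthetic multi-ethnic cohort generation.

Generates cohort tables with the joint statistical structure of a
community-dwelling Singaporean population aged 60 and above (Chinese,
Indian, Malay; both sexes): per-cell marginal means/SDs, linear age
trends, and a documented cross-variable correlation structure.  The
defaults encode the published descriptive statistics of the PIONEER-style
study cohort so that every downstream stage (soft-tissue conversion,
strength simulation, trajectory statistics, risk classification) is
testable without any data download.

Only the marginals are calibrated against published numbers; the
correlation matrix and age-trend slopes are explicit modelling choices
(see ``DEFAULT_CORRELATIONS`` / ``DEFAULT_AGE_SLOPES``) and are fully
overridable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SEXES = ("male", "female")
ETHNICITIES = ("Chinese", "Indian", "Malay")

#: Variables drawn from the per-cell truncated multivariate normal.
#: ``bmi``, ``t_score`` and ``tstt_standing`` are derived, never drawn.
DRAWN_VARIABLES = ("age", "weight", "height", "tstt_sup", "frax_hfp", "abmd", "strength")

#: Lower/upper truncation bounds for each drawn variable.
TRUNCATION_BOUNDS = {
    "age": (60.0, np.inf),
    "weight": (0.0, np.inf),
    "height": (0.0, np.inf),
    "tstt_sup": (0.0, np.inf),
    "frax_hfp": (0.0, 100.0),
    "abmd": (0.0, np.inf),
    "strength": (0.0, np.inf),
}


@dataclass
class SubjectRecord:
    """One cohort row: demographics plus bone-health biomarkers.

    Units: age years, weight kg, height cm, bmi kg/m^2, abmd g/cm^2
    (total hip), frax_hfp % (10-year hip-fracture probability), TSTT cm,
    strength kN.
    """

    id: str
    age: float
    sex: str
    ethnicity: str
    weight: float
    height: float
    bmi: float
    abmd: float
    t_score: float
    frax_hfp: float
    tstt_sup: float
    tstt_standing: float | None = None
    strength: float | None = None

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.age < 60:
            raise ValueError("cohort is aged 60 and above")
        for name in ("weight", "height", "abmd", "frax_hfp", "tstt_sup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frax_hfp > 100:
            raise ValueError("frax_hfp is a percentage <= 100")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 1e-9:
            raise ValueError("bmi inconsistent with weight/height")


@dataclass
class CellParams:
    """Marginal means/SDs for one (sex, ethnicity) cell."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("cell size n must be >= 0")
        for v in DRAWN_VARIABLES:
            if v not in self.means or v not in self.sds:
                raise ValueError(f"cell is missing marginal for {v!r}")
            if self.sds[v] < 0:
                raise ValueError(f"sd for {v!r} must be >= 0")


# Published per-cell descriptive statistics (mean, sd).  The table's TSTT
# column is the measured supine thickness (its values are incompatible
# with the standing-conversion intercepts, so it cannot be the standing
# quantity); standing TSTT is derived downstream.
_TABLE = {
    # sex, ethnicity: n, age, weight, height, bmi, tstt_sup, frax_hfp, abmd, t_score, strength
    ("male", "Chinese"): (494, (73.70, 8.14), (65.29, 10.65), (164.66, 6.74), (24.09, 3.87),
                          (2.31, 0.60), (2.56, 2.05), (0.86, 0.13), (-1.57, 1.00), (4.56, 1.76)),
    ("male", "Indian"): (213, (73.32, 8.82), (71.17, 14.33), (166.01, 7.06), (25.71, 4.32),
                         (3.13, 0.69), (1.34, 1.27), (0.95, 0.15), (-0.88, 1.20), (5.89, 2.28)),
    ("male", "Malay"): (273, (73.10, 8.31), (70.37, 13.30), (164.12, 6.41), (26.08, 4.47),
                        (2.99, 0.67), (1.52, 1.34), (0.91, 0.14), (-1.22, 1.08), (5.05, 1.82)),
    ("female", "Chinese"): (594, (74.20, 8.30), (55.08, 9.50), (152.84, 6.06), (23.57, 3.83),
                            (2.95, 0.92), (5.64, 5.03), (0.72, 0.11), (-1.64, 0.99), (3.54, 1.13)),
    ("female", "Indian"): (305, (74.67, 8.61), (62.74, 12.84), (152.07, 6.70), (27.07, 4.98),
                           (4.21, 1.06), (2.66, 2.67), (0.78, 0.13), (-1.13, 1.11), (4.06, 1.39)),
    ("female", "Malay"): (325, (71.91, 8.01), (63.46, 15.39), (149.41, 6.12), (28.35, 6.31),
                          (4.25, 1.37), (3.14, 4.01), (0.75, 0.13), (-1.43, 1.12), (3.55, 1.24)),
}

#: Published pooled (per-sex) cells; used for consistency checks only.
POOLED_TABLE = {
    "male": {"n": 980, "age": (73.45, 8.34), "weight": (67.98, 12.58),
             "height": (164.80, 6.75), "bmi": (25.00, 4.24), "tstt_sup": (2.68, 0.74),
             "frax_hfp": (2.00, 1.81), "abmd": (0.89, 0.14), "t_score": (-1.32, 1.10),
             "strength": (4.99, 1.97)},
    "female": {"n": 1224, "age": (73.71, 8.37), "weight": (59.21, 12.79),
               "height": (151.74, 6.40), "bmi": (25.71, 5.32), "tstt_sup": (3.61, 1.27),
               "frax_hfp": (4.23, 4.50), "abmd": (0.75, 0.12), "t_score": (-1.46, 1.08),
               "strength": (3.67, 1.25)},
}

#: Recruitment accounting: enrolled with DXA+FRAX available, then scans
#: with motion artifacts and strength-model failures excluded.
EXCLUSION_COUNTS = {"initial": 2235, "motion_artifacts": 18, "model_errors": 13}

#: Default cross-variable correlations among *residuals* (age removed).
#: Not calibrated against published data: plausible, documented choices.
DEFAULT_CORRELATIONS = {
    ("abmd", "strength"): 0.7,
    ("abmd", "frax_hfp"): -0.5,
    ("tstt_sup", "weight"): 0.6,
}

#: Linear age-trend slopes (units of the variable per year); signs follow
#: the observed trajectories (density, soft tissue and strength decline
#: with age, hip-fracture probability rises).
DEFAULT_AGE_SLOPES = {
    "abmd": -0.004,
    "strength": -0.06,
    "frax_hfp": 0.08,
    "tstt_sup": -0.02,
}

#: Young-adult reference (mean, sd) in g/cm^2 mapping aBMD to T-score,
#: per sex; method-of-moments fit to the pooled published marginals so
#: the derived T-score reproduces the printed mean/SD.
DEFAULT_TSCORE_REFERENCE = {
    "male": (1.058, 0.1273),
    "female": (0.9122, 0.1111),
}


def _default_cells() -> dict:
    cells = {}
    keys = ("age", "weight", "height", "bmi", "tstt_sup", "frax_hfp", "abmd", "t_score", "strength")
    for (sex, eth), row in _TABLE.items():
        n = row[0]
        means = {k: row[i + 1][0] for i, k in enumerate(keys)}
        sds = {k: row[i + 1][1] for i, k in enumerate(keys)}
        cells[(sex, eth)] = CellParams(n=n, means=means, sds=sds)
    return cells


@dataclass
class CohortParams:
    """Full generator parameterisation.

    ``cells`` maps (sex, ethnicity) to marginal means/SDs; ``corr`` holds
    pairwise residual correlations for drawn variables; ``age_slopes``
    are linear conditional-mean slopes per year; ``tscore_reference``
    is the per-sex young-adult (mean, sd) used to derive T-score from
    aBMD; ``truncate`` applies the physical bounds by rejection.
    """

    cells: dict = field(default_factory=_default_cells)
    corr: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    tscore_reference: dict = field(default_factory=lambda: dict(DEFAULT_TSCORE_REFERENCE))
    truncate: bool = True
    seed: int | None = None

    def validate(self) -> None:
        for cell in self.cells.values():
            cell.validate()
        resid = _residual_corr_matrix(self.corr)
        eig = np.linalg.eigvalsh(resid)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")

    def replace(self, **kw) -> "CohortParams":
        return dataclasses.replace(self, **kw)


_RESIDUAL_VARS = tuple(v for v in DRAWN_VARIABLES if v != "age")


def _residual_corr_matrix(corr_pairs: dict) -> np.ndarray:
    k = len(_RESIDUAL_VARS)
    idx = {v: i for i, v in enumerate(_RESIDUAL_VARS)}
    mat = np.eye(k)
    for (a, b), r in corr_pairs.items():
        if a == "age" or b == "age":
            raise ValueError("age correlations are expressed through age_slopes")
        if a not in idx or b not in idx:
            raise ValueError(f"unknown variable in correlation pair ({a!r}, {b!r})")
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlation outside [-1, 1]")
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    return mat


def _draw_cell(cell: CellParams, params: CohortParams, n: int,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sample ``n`` joint rows for one cell.

    Age is drawn first (truncated at 60 when requested); other variables
    get a linear-in-age conditional mean plus a correlated Gaussian
    residual whose variance is shrunk so the marginal SD matches the
    cell target.  Physical bounds are enforced by rejection.
    """
    if n == 0:
        return {v: np.zeros(0) for v in DRAWN_VARIABLES}

    corr = _residual_corr_matrix(params.corr)
    mu_age, sd_age = cell.means["age"], cell.sds["age"]

    slopes = np.array([params.age_slopes.get(v, 0.0) for v in _RESIDUAL_VARS])
    sds = np.array([cell.sds[v] for v in _RESIDUAL_VARS])
    means = np.array([cell.means[v] for v in _RESIDUAL_VARS])
    trend_var = (slopes * sd_age) ** 2
    resid_var = sds**2 - trend_var
    if np.any(resid_var < 0):
        bad = _RESIDUAL_VARS[int(np.argmin(resid_var))]
        raise ValueError(f"age slope for {bad!r} implies more variance than the marginal sd")
    resid_sd = np.sqrt(resid_var)
    cov = corr * np.outer(resid_sd, resid_sd)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))

    out = {v: [] for v in DRAWN_VARIABLES}
    accepted = 0
    max_rounds = 200
    for _ in range(max_rounds):
        m = max(n - accepted, 0)
        if m == 0:
            break
        batch = int(np.ceil(m * 1.6)) + 8
        age = rng.normal(mu_age, sd_age, size=batch)
        z = rng.standard_normal(size=(batch, len(_RESIDUAL_VARS)))
        vals = means + slopes * (age - mu_age)[:, None] + z @ chol.T
        cols = {"age": age}
        cols.update({v: vals[:, i] for i, v in enumerate(_RESIDUAL_VARS)})
        if params.truncate:
            ok = np.ones(batch, dtype=bool)
            for v in DRAWN_VARIABLES:
                lo, hi = TRUNCATION_BOUNDS[v]
                ok &= (cols[v] >= lo) & (cols[v] <= hi)
        else:
            ok = np.ones(batch, dtype=bool)
        take = min(int(ok.sum()), m)
        sel = np.flatnonzero(ok)[:take]
        for v in DRAWN_VARIABLES:
            out[v].append(cols[v][sel])
        accepted += take
    if accepted < n:
        raise RuntimeError("rejection sampling failed to reach the requested cell size")
    return {v: np.concatenate(out[v]) for v in DRAWN_VARIABLES}


def generate_cohort(params: CohortParams, n_override: int | None = None,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Generate a synthetic cohort as a list of :class:`SubjectRecord`.

    ``n_override`` replaces every cell's size (useful for scaled-down
    tests); identical ``(params, seed)`` yield identical output.  The
    derived fields are filled as bmi = weight/height^2 and T-score =
    (aBMD - ref_mean)/ref_sd; standing TSTT is left for the soft-tissue
    module.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    if n_override is not None and n_override < 0:
        raise ValueError("n_override must be >= 0")

    order = [(s, e) for s in SEXES for e in ETHNICITIES if (s, e) in params.cells]
    streams = np.random.SeedSequence(seed).spawn(len(order))
    records: list[SubjectRecord] = []
    for (sex, eth), ss in zip(order, streams):
        cell = params.cells[(sex, eth)]
        n = cell.n if n_override is None else n_override
        rng = np.random.default_rng(ss)
        cols = _draw_cell(cell, params, n, rng)
        ref_mean, ref_sd = params.tscore_reference[sex]
        for i in range(n):
            w, h = float(cols["weight"][i]), float(cols["height"][i])
            records.append(SubjectRecord(
                id=f"{sex[0].upper()}{eth[:2].upper()}{i:05d}",
                age=float(cols["age"][i]),
                sex=sex,
                ethnicity=eth,
                weight=w,
                height=h,
                bmi=w / (h / 100.0) ** 2,
                abmd=float(cols["abmd"][i]),
                t_score=(float(cols["abmd"][i]) - ref_mean) / ref_sd,
                frax_hfp=float(cols["frax_hfp"][i]),
                tstt_sup=float(cols["tstt_sup"][i]),
                strength=float(cols["strength"][i]),
            ))
    return records


def cohort_to_frame(records: list[SubjectRecord]):
    """Convert records to a pandas DataFrame (one row per subject)."""
    import pandas as pd

    cols = [f.name for f in dataclasses.fields(SubjectRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def frame_to_cohort(df) -> list[SubjectRecord]:
    """Convert a DataFrame (see :func:`cohort_to_frame`) back to records."""
    names = {f.name for f in dataclasses.fields(SubjectRecord)}
    out = []
    for _, row in df.iterrows():
        kw = {k: row[k] for k in names if k in df.columns}
        missing = {"tstt_standing", "strength"} - set(kw)
        for m in missing:
            kw[m] = None
        out.append(SubjectRecord(**kw))
    return out
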