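"""Synthetic family and unrelated cohorts with planted lipidomic risk effects.

Emulates the structure of the two study designs the pipeline targets:

* a multigenerational pedigree cohort (default ~40 three-generation
  families, ~770 subjects) followed for up to ~23 years with usable
  (exact) incident-T2D event times; and
* an unrelated validation cohort (default ~644 subjects) where only
  end-of-follow-up diabetes status and person-time are recorded, as when
  the exact diagnosis date is unknown.

Plasma concentrations for ``n_lipid_species`` lipid species are generated
with a polygenic (familial) component -- per species, covariance
``h2 * R + (1 - h2) * I`` on the latent scale with R the relationship
matrix -- plus an optional shared within-block factor, then mapped to
log-normal concentrations to mimic the wide inter-individual variability
of plasma lipidomes.  A small set of candidate species carries planted
proportional-hazards effects (log hazard ratios per SD of the
inverse-normal concentration); all other species are null.  Incident
diabetes times follow an exponential (optionally Weibull) proportional
hazards law, so an oracle Cox fit on a large simulation recovers the
planted coefficients.

Everything is driven by a single integer seed: identical configurations
produce identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_relationship_matrix
from .transforms import inverse_normalize

#: Planted candidate species: the three signal species (log-HR per SD on the
#: inverse-normal scale, signs +/-/+ for the dihydroceramide,
#: lyso-alkyl-PC and triacylglycerol respectively) among ten candidates.
DEFAULT_PLANTED = {
    "Cer(d18:0/18:0)": 0.42,
    "LPC(O-22:1)": -0.34,
    "TG(16:0_18:0_18:1)": 0.54,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults approximate the target designs: ~40 extended families
    totalling ~770 subjects followed up to 23 years with a baseline
    incidence near 0.013 events per person-year, 319 lipid species of
    which 10 are screening candidates and 3 carry planted effects, and an
    unrelated cohort of 644 subjects with interval follow-up only.
    """

    n_families: int = 42
    mean_sibship: float = 3.8
    n_unrelated: int = 644
    n_lipid_species: int = 319
    n_candidate_species: int = 10
    planted_species: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    lipid_heritability: float = 0.35
    lipid_block_correlation: float = 0.2
    lipid_block_size: int = 10
    baseline_hazard: float = 0.013
    weibull_shape: float = 1.0
    dropout_rate: float = 0.06
    visit_interval_years: float = 5.0
    max_followup_years: float = 23.0
    event_time_convention: str = "exact"  # exact | interval_midpoint | visit
    covariate_log_hr: dict = field(
        default_factory=lambda: {"age": 0.025, "bmi": 0.04, "prediabetes": 0.9}
    )
    prediabetes_intercept: float = -2.0
    prediabetes_age_coef: float = 0.02
    prediabetes_bmi_coef: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 0:
            raise ValueError("n_families must be non-negative")
        if not 0 <= self.lipid_heritability <= 1:
            raise ValueError("lipid_heritability must lie in [0, 1]")
        if not 0 <= self.lipid_block_correlation < 1:
            raise ValueError("lipid_block_correlation must lie in [0, 1)")
        if self.baseline_hazard < 0 or self.visit_interval_years <= 0:
            raise ValueError("rates and intervals must be positive")
        if self.event_time_convention not in ("exact", "interval_midpoint", "visit"):
            raise ValueError("unknown event_time_convention")
        if self.n_candidate_species > self.n_lipid_species:
            raise ValueError("more candidates than species")
        if len(self.planted_species) > self.n_candidate_species:
            raise ValueError("planted species must be a subset of candidates")

    @property
    def species_names(self) -> list:
        names = list(self.planted_species)
        k = len(names) + 1
        while len(names) < self.n_lipid_species:
            names.append(f"SPECIES_{k:03d}")
            k += 1
        return names[: self.n_lipid_species]

    @property
    def candidate_names(self) -> list:
        return self.species_names[: self.n_candidate_species]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------


def _make_families(config: SimulationConfig, rng) -> Pedigree:
    """Three-generation families: founder couple, sibship, married-in
    spouses, grandchildren.  Sibship sizes are Poisson(mean_sibship)
    truncated at 1."""
    rows = []
    fam_of = {}
    for f in range(config.n_families):
        tag = f"F{f + 1:03d}"
        gp_f, gp_m = f"{tag}_GF", f"{tag}_GM"
        rows += [(gp_f, None, None, 1), (gp_m, None, None, 2)]
        fam_of[gp_f] = fam_of[gp_m] = tag
        n_kids = max(1, int(rng.poisson(config.mean_sibship)))
        for c in range(n_kids):
            kid = f"{tag}_C{c + 1}"
            sex = int(rng.integers(1, 3))
            rows.append((kid, gp_f, gp_m, sex))
            fam_of[kid] = tag
            if rng.random() < 0.8:  # most children marry in a spouse
                sp = f"{tag}_S{c + 1}"
                rows.append((sp, None, None, 3 - sex))
                fam_of[sp] = tag
                n_g = int(rng.poisson(max(config.mean_sibship - 1, 0.5)))
                for g in range(n_g):
                    gkid = f"{tag}_C{c + 1}G{g + 1}"
                    fa, mo = (kid, sp) if sex == 1 else (sp, kid)
                    rows.append((gkid, fa, mo, int(rng.integers(1, 3))))
                    fam_of[gkid] = tag
    df = pd.DataFrame(rows, columns=["id", "father", "mother", "sex"])
    ped = Pedigree(df)
    ped.family_of = fam_of
    return ped


# ---------------------------------------------------------------------------
# lipids, covariates, outcomes
# ---------------------------------------------------------------------------


def _simulate_lipids(config: SimulationConfig, rng, relationship=None, n=None) -> pd.DataFrame:
    """Log-normal concentrations with polygenic + block-factor latent scale."""
    if relationship is not None:
        R = np.asarray(relationship, dtype=float)
        n = R.shape[0]
        evals, evecs = np.linalg.eigh(R)
        L = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    else:
        L = None
    h2 = config.lipid_heritability
    rho = config.lipid_block_correlation
    p = config.n_lipid_species
    n_blocks = int(np.ceil(p / config.lipid_block_size))
    block_of = np.repeat(np.arange(n_blocks), config.lipid_block_size)[:p]
    block_factor = rng.normal(size=(n, n_blocks))
    Z = np.empty((n, p))
    for j in range(p):
        g = (L @ rng.normal(size=n)) if (L is not None and h2 > 0) else rng.normal(size=n)
        e = rng.normal(size=n)
        latent = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
        if rho > 0:
            latent = np.sqrt(rho) * block_factor[:, block_of[j]] + np.sqrt(1 - rho) * latent
        Z[:, j] = latent
    # species-specific log-normal marginals (wide inter-individual spread)
    log_mu = rng.uniform(-1.0, 3.0, size=p)
    log_sd = rng.uniform(0.3, 0.9, size=p)
    conc = np.exp(log_mu + log_sd * Z)
    return pd.DataFrame(conc, columns=config.species_names)


def _simulate_covariates(config: SimulationConfig, rng, n) -> pd.DataFrame:
    age = rng.uniform(20, 65, n)
    sex = rng.integers(0, 2, n)  # 1 = male
    bmi = np.clip(rng.normal(29, 5.5, n), 16, 55)
    waist = np.clip(72 + 2.1 * (bmi - 22) + rng.normal(0, 6, n), 55, 160)
    sbp = np.clip(rng.normal(118 + 0.3 * (age - 40), 13, n), 85, 210)
    dbp = np.clip(0.6 * sbp + rng.normal(0, 7, n), 45, 130)
    total_chol = np.clip(rng.normal(4.9 + 0.01 * (age - 40), 0.9, n), 2.2, 9.5)
    hdl_chol = np.clip(rng.normal(1.25 - 0.1 * sex, 0.28, n), 0.4, 3.0)
    trig = np.exp(rng.normal(0.45 + 0.012 * (bmi - 27), 0.45, n))
    lp = (
        config.prediabetes_intercept
        + config.prediabetes_age_coef * (age - 40)
        + config.prediabetes_bmi_coef * (bmi - 27)
    )
    prediab = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    fpg = np.where(prediab == 1, rng.uniform(100, 125, n), rng.uniform(78, 99, n))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "waist": waist,
            "sbp": sbp,
            "dbp": dbp,
            "total_chol": total_chol,
            "hdl_chol": hdl_chol,
            "triglycerides": trig,
            "antilipid_drug": rng.integers(0, 2, n) * (rng.random(n) < 0.25),
            "antihtn_drug": rng.integers(0, 2, n) * (rng.random(n) < 0.3),
            "family_history_t2d": (rng.random(n) < 0.35).astype(int),
            "prediabetes": prediab,
            "glycemic_class": np.where(prediab == 1, "prediabetes", "NGT"),
            "fpg": fpg,
        }
    )


def _linear_predictor(config: SimulationConfig, lipids: pd.DataFrame, cov: pd.DataFrame):
    """Planted log-hazard linear predictor on the inverse-normal scale."""
    eta = np.zeros(len(lipids))
    for sp, beta in config.planted_species.items():
        eta += beta * inverse_normalize(lipids[sp].to_numpy(), name=sp).values
    c = config.covariate_log_hr
    eta += c.get("age", 0.0) * (cov["age"].to_numpy() - 40)
    eta += c.get("bmi", 0.0) * (cov["bmi"].to_numpy() - 27)
    eta += c.get("prediabetes", 0.0) * cov["prediabetes"].to_numpy()
    return eta


def _event_times(config: SimulationConfig, rng, eta):
    """Inverse-CDF draw from the Weibull PH law H(t) = h0 * t^k * exp(eta)."""
    u = rng.random(len(eta))
    k = config.weibull_shape
    base = -np.log(u) / (config.baseline_hazard * np.exp(eta))
    return base ** (1.0 / k)


def planted_linear_predictor(config: SimulationConfig, cohort: pd.DataFrame):
    """Recompute the planted lipid-only linear predictor for a cohort table."""
    eta = np.zeros(len(cohort))
    for sp, beta in config.planted_species.items():
        eta += beta * inverse_normalize(cohort[sp].to_numpy(), name=sp).values
    return eta


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def simulate_pedigree_cohort(config: SimulationConfig):
    """Simulate the family cohort.

    Returns
    -------
    cohort : pandas.DataFrame
        One row per subject: ids, family, covariates, lipid species,
        glycemic class, exact event/censoring time (``time``) and incident
        diabetes indicator (``event``).
    pedigree : Pedigree
        The generating pedigree (relationship matrix via
        :func:`lipidrisk.build_relationship_matrix`).
    """
    if config.n_families == 0:
        raise ValueError("cannot simulate a pedigree cohort with zero families")
    rng = np.random.default_rng(config.seed)
    ped = _make_families(config, rng)
    R = build_relationship_matrix(ped)
    n = len(ped.ids)
    lipids = _simulate_lipids(config, rng, relationship=R.to_numpy())
    cov = _simulate_covariates(config, rng, n)
    eta = _linear_predictor(config, lipids, cov)
    T = _event_times(config, rng, eta)
    dropout = (
        rng.exponential(1.0 / config.dropout_rate, n)
        if config.dropout_rate > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(dropout, config.max_followup_years)
    event = (T <= censor).astype(int)
    time = np.where(event == 1, T, censor)
    if config.event_time_convention != "exact":
        width = config.visit_interval_years
        k = np.ceil(time / width)
        shift = 0.5 if config.event_time_convention == "interval_midpoint" else 0.0
        time = np.where(event == 1, (k - shift) * width, time)
    time = np.maximum(time, 1e-6)
    cohort = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": ped.ids,
                    "family_id": [ped.family_of[i] for i in ped.ids],
                }
            ),
            cov,
            lipids,
        ],
        axis=1,
    )
    cohort["time"] = time
    cohort["event"] = event
    return cohort, ped


def simulate_unrelated_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the unrelated validation cohort.

    Outcomes are recorded as end-of-follow-up status only: ``event`` is 1
    when diabetes developed at any point during the subject's follow-up
    and ``person_years`` is the full observed follow-up length (the exact
    onset date is treated as unknown, as in interval-detected cohorts).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_unrelated
    if n == 0:
        return pd.DataFrame(
            columns=["subject_id", "person_years", "event"]
        )
    lipids = _simulate_lipids(config, rng, relationship=None, n=n)
    cov = _simulate_covariates(config, rng, n)
    eta = _linear_predictor(config, lipids, cov)
    T = _event_times(config, rng, eta)
    followup = rng.uniform(
        config.visit_interval_years, min(config.max_followup_years, 13.0), n
    )
    event = (T <= followup).astype(int)
    cohort = pd.concat(
        [pd.DataFrame({"subject_id": [f"U{i + 1:04d}" for i in range(n)]}), cov, lipids],
        axis=1,
    )
    cohort["person_years"] = followup
    cohort["event"] = event
    return cohort


def simulate_ir_measures(
    cohort: pd.DataFrame, coupling: float, config: SimulationConfig | None = None, seed=None
) -> pd.DataFrame:
    """Add fasting insulin, leptin and adiponectin coupled to the lipid signal.

    ``coupling`` in [-1, 1] sets the latent correlation between the
    planted-species linear predictor and the insulin-resistance axis:
    0 gives independence, positive values make fasting insulin, leptin and
    the leptin/adiponectin ratio increase (and adiponectin decrease) with
    the lipid score.  Fasting glucose is kept consistent with the baseline
    glycemic class and is not modified.
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    out = cohort.copy()
    n = len(out)
    lp = planted_linear_predictor(config, out)
    sd = lp.std()
    z = (lp - lp.mean()) / sd if sd > 0 else np.zeros(n)
    latent = coupling * z + np.sqrt(1 - coupling**2) * rng.normal(size=n)
    out["fpi"] = np.exp(np.log(9.0) + 0.45 * latent + 0.15 * rng.normal(size=n))
    out["leptin"] = np.exp(
        np.log(12.0) + 0.5 * latent + 0.06 * (out["bmi"] - 27) + 0.2 * rng.normal(size=n)
    )
    out["adiponectin"] = np.exp(np.log(8.0) - 0.35 * latent + 0.2 * rng.normal(size=n))
    return out


def write_cohort(cohort: pd.DataFrame, path, sep=",") -> None:
    """Write a cohort table as CSV/TSV (column dictionary in docs)."""
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort(path, sep=",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
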