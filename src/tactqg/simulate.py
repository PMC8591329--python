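"""Forward simulator of a two-generation, tactic-structured pedigree.

Generative model
----------------
Each individual carries a four-component standardized breeding-value vector
``(a_f, a_h, a_j, a_L)``: tactic-specific expressions of length in the
female, hooknose and jack contexts, plus an additive liability component
for the male maturation threshold.  Founders draw the vector from a
zero-mean multivariate normal whose 3×3 length block has correlation
matrix ``r_G`` (unit diagonal, PSD); the liability component is by default
uncorrelated with the length expressions.  Offspring receive the
mid-parent vector plus an independent Mendelian-segregation deviate with
half the founder covariance, so breeding-value variance is conserved
across generations.

Phenotype in tactic ``t``::

    length = mu_t + sqrt(h2_t) * sd_t * a_t + e,   e ~ N(0, (1 - h2_t) * sd_t^2)

Males mature as jacks iff the liability
``L = sqrt(h2_liab) * a_L + sqrt(1 - h2_liab) * eps`` (a standard normal
marginally) exceeds the normal quantile implied by ``jack_fraction``.

Reproductive success is Poisson with
``log E[rs] = b0_t + b1_t * x + b2_t * x**2`` where ``x`` is length
standardized within tactic.  Parents are sampled (dams and sires
independently, with replacement) with probability proportional to their
drawn rs, and the rs written into the emitted pedigree for parents is the
*realized* offspring count, matching the "offspring that returned to
spawn" semantics of the study's fitness measure.

Under this model the expected single parent–offspring regression recovers
``h2 = 2 b`` within a tactic and ``r_G(o,p) * h_o * h_p`` after the
``sigma_p/sigma_o`` correction between tactics, which is what makes the
simulator a quantitative oracle for the heritability machinery.

Randomness: a single :class:`numpy.random.Generator` (PCG64) seeded from
``SimConfig.seed`` is threaded through founders → founder fitness →
mating/segregation → offspring fitness, in that fixed order; identical
configs and seeds give byte-identical pedigrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ConfigError
from .pedigree import Pedigree, TACTICS

__all__ = ["SimConfig", "simulate_founders", "assign_fitness", "mate_and_breed", "simulate_pedigree"]

TACTIC_INDEX = {"female": 0, "hooknose": 1, "jack": 2}
_LIAB = 3  # index of the liability component in the genetic vector

# Default phenotypic SDs reconstruct the study population's variance
# structure: female SD ~ 48 mm, with hooknose:female variance ratio
# 1/0.415 and hooknose:jack ratio 2.77 (=> hooknose ~ 74.5 mm, jack ~ 44.8).
_DEF_MEANS = {"female": 733.0, "hooknose": 735.0, "jack": 423.0}
_DEF_SDS = {"female": 48.0, "hooknose": 74.5, "jack": 44.8}
_DEF_H2 = {"female": 0.36, "hooknose": 0.87, "jack": 0.47}
# log-scale fitness: intercepts from per-tactic mean reproductive success,
# linear terms from the pooled-years directional gradients, weak curvature.
_DEF_SELECTION = {
    "female": (float(np.log(2.61)), 0.142, -0.019),
    "hooknose": (float(np.log(2.80)), 0.239, 0.004),
    "jack": (float(np.log(1.21)), 0.098, 0.043),
}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic two-generation pedigree.

    Defaults emulate the Calapooya Creek study population: ~300 dams and
    ~320 sires (18% jacks) returning in 2002–2003 producing 775 offspring
    returning in 2004–2006, tactic length means/SDs and mean reproductive
    successes as printed, per-tactic heritabilities at the study's point
    estimates, and no intertactical genetic correlation.
    """

    n_dams: int = 301
    n_sires: int = 322
    jack_fraction: float = 0.18
    n_offspring: int = 775
    tactic_means_mm: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_MEANS))
    tactic_sd_mm: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_SDS))
    h2: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_H2))
    #: 3×3 correlation matrix of tactic-expressed length breeding values
    #: (order female, hooknose, jack); unit diagonal, positive semidefinite.
    r_G: np.ndarray = field(default_factory=lambda: np.eye(3))
    tactic_liability_h2: float = 0.9
    #: per-tactic (b0, b1, b2): log mean rs as a function of standardized length
    selection: Mapping[str, tuple] = field(default_factory=lambda: dict(_DEF_SELECTION))
    parent_years: Sequence[int] = (2002, 2003)
    offspring_years: Sequence[int] = (2004, 2005, 2006)
    seed: int = 0

    def __post_init__(self):
        self.r_G = np.asarray(self.r_G, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_dams < 1 or self.n_sires < 1 or self.n_offspring < 1:
            raise ConfigError("n_dams, n_sires and n_offspring must be positive")
        if not 0 < self.jack_fraction < 1:
            raise ConfigError(f"jack_fraction must be in (0,1), got {self.jack_fraction}")
        if self.r_G.shape != (3, 3):
            raise ConfigError(f"r_G must be 3x3, got {self.r_G.shape}")
        if not np.allclose(self.r_G, self.r_G.T):
            raise ConfigError("r_G must be symmetric")
        if not np.allclose(np.diag(self.r_G), 1.0):
            raise ConfigError("r_G must have a unit diagonal")
        if np.linalg.eigvalsh(self.r_G).min() < -1e-8:
            raise ConfigError("r_G must be positive semidefinite")
        for t in TACTICS:
            if self.tactic_sd_mm[t] <= 0:
                raise ConfigError(f"tactic_sd_mm[{t!r}] must be positive")
            if not 0 <= self.h2[t] <= 1:
                raise ConfigError(f"h2[{t!r}] must be in [0,1]")
        if not 0 <= self.tactic_liability_h2 <= 1:
            raise ConfigError("tactic_liability_h2 must be in [0,1]")
        if max(self.parent_years) >= min(self.offspring_years):
            raise ConfigError("parent years must precede offspring years")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["r_G"] = np.asarray(self.r_G).tolist()
        d["parent_years"] = list(self.parent_years)
        d["offspring_years"] = list(self.offspring_years)
        d["tactic_means_mm"] = dict(self.tactic_means_mm)
        d["tactic_sd_mm"] = dict(self.tactic_sd_mm)
        d["h2"] = dict(self.h2)
        d["selection"] = {k: list(v) for k, v in self.selection.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "selection" in d:
            d["selection"] = {k: tuple(v) for k, v in d["selection"].items()}
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad simulation config: {exc}") from None

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _genetic_root(cfg: SimConfig) -> np.ndarray:
    """Symmetric square root of the 4×4 breeding-value correlation matrix.

    Eigen-based so that singular-but-PSD ``r_G`` (e.g. perfect correlation)
    is handled; deterministic for a given matrix.
    """
    R = np.eye(4)
    R[:3, :3] = cfg.r_G
    w, V = np.linalg.eigh(R)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _draw_genetics(n: int, root: np.ndarray, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    return rng.standard_normal((n, 4)) @ (root * scale).T


def _phenotype(cfg: SimConfig, tactic: np.ndarray, A: np.ndarray, rng: np.random.Generator):
    """Length = mu_t + sqrt(h2_t) sd_t a_t + e; returns (length, e)."""
    n = len(tactic)
    e = np.empty(n)
    length = np.empty(n)
    eps = rng.standard_normal(n)
    for t in TACTICS:
        m = tactic == t
        if not m.any():
            continue
        sd, h2 = cfg.tactic_sd_mm[t], cfg.h2[t]
        e[m] = np.sqrt(max(0.0, 1.0 - h2)) * sd * eps[m]
        length[m] = cfg.tactic_means_mm[t] + np.sqrt(h2) * sd * A[m, TACTIC_INDEX[t]] + e[m]
    return length, e


def _male_tactic(cfg: SimConfig, a_liab: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h2l = cfg.tactic_liability_h2
    liab = np.sqrt(h2l) * a_liab + np.sqrt(1.0 - h2l) * rng.standard_normal(len(a_liab))
    thr = norm.ppf(1.0 - cfg.jack_fraction)
    return np.where(liab > thr, "jack", "hooknose")


def simulate_founders(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Founder (parent-generation) records with latent genetic columns.

    Columns: sex, tactic, year, length_mm plus latent ``a_f .. a_l`` and
    the environmental deviate ``e``.  Dams come first, then sires.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_dams + cfg.n_sires
    root = _genetic_root(cfg)
    A = _draw_genetics(n, root, rng)
    sex = np.array(["female"] * cfg.n_dams + ["male"] * cfg.n_sires)
    tactic = np.empty(n, dtype=object)
    tactic[: cfg.n_dams] = "female"
    tactic[cfg.n_dams:] = _male_tactic(cfg, A[cfg.n_dams:, _LIAB], rng)
    length, e = _phenotype(cfg, tactic, A, rng)
    year = rng.choice(np.asarray(cfg.parent_years), size=n)
    return pd.DataFrame({
        "sex": sex, "tactic": tactic, "year": year, "length_mm": length,
        "a_f": A[:, 0], "a_h": A[:, 1], "a_j": A[:, 2], "a_l": A[:, _LIAB], "e": e,
    })


def assign_fitness(records: pd.DataFrame, cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw Poisson reproductive success from the tactic-specific fitness model.

    ``log E[rs] = b0_t + b1_t x + b2_t x^2`` with ``x`` the within-tactic
    standardized length (sample mean/SD of the records passed in; a group
    with fewer than 2 members or zero spread gets x = 0).
    """
    out = records.copy()
    lam = np.empty(len(out))
    for t in TACTICS:
        m = (out["tactic"] == t).to_numpy()
        if not m.any():
            continue
        b0, b1, b2 = cfg.selection[t]
        length = out.loc[m, "length_mm"].astype(float).to_numpy()
        sd = length.std(ddof=1) if m.sum() > 1 else 0.0
        x = (length - length.mean()) / sd if sd > 0 else np.zeros_like(length)
        lam[m] = np.exp(b0 + b1 * x + b2 * x * x)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    out["rs"] = rng.poisson(lam)
    return out


def mate_and_breed(parents: pd.DataFrame, cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample matings ∝ parental rs and produce the offspring generation.

    Returns ``(offspring, parents)`` where the parents frame has its ``rs``
    replaced by the *realized* offspring counts.  Offspring inherit the
    mid-parent breeding-value vector plus a Mendelian deviate with half the
    founder covariance; sex is Bernoulli(1/2) and male tactic follows the
    liability rule.  Offspring rs is drawn from the fitness model.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    dams = parents[parents["sex"].eq("female")].reset_index()
    sires = parents[parents["sex"].eq("male")].reset_index()
    if dams.empty or sires.empty:
        raise ConfigError("need at least one dam and one sire")
    wd = dams["rs"].astype(float).to_numpy()
    ws = sires["rs"].astype(float).to_numpy()
    if wd.sum() == 0 or ws.sum() == 0:
        raise ConfigError("all dams or all sires have rs = 0; no matings possible")

    n = cfg.n_offspring
    di = rng.choice(len(dams), size=n, p=wd / wd.sum())
    si = rng.choice(len(sires), size=n, p=ws / ws.sum())

    acols = ["a_f", "a_h", "a_j", "a_l"]
    Ad = dams.loc[di, acols].to_numpy()
    As = sires.loc[si, acols].to_numpy()
    root = _genetic_root(cfg)
    mendelian = _draw_genetics(n, root, rng, scale=np.sqrt(0.5))
    A = 0.5 * (Ad + As) + mendelian

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    tactic = np.where(sex == "female", "female", "")
    males = sex == "male"
    # liability epsilon is drawn for every offspring to keep the stream
    # layout independent of the realized sex ratio
    male_tactic = _male_tactic(cfg, A[:, _LIAB], rng)
    tactic = np.where(males, male_tactic, "female")
    length, e = _phenotype(cfg, tactic, A, rng)
    year = rng.choice(np.asarray(cfg.offspring_years), size=n)

    offspring = pd.DataFrame({
        "sex": sex, "tactic": tactic, "year": year, "length_mm": length,
        "dam_index": di, "sire_index": si,
        "a_f": A[:, 0], "a_h": A[:, 1], "a_j": A[:, 2], "a_l": A[:, _LIAB], "e": e,
    })
    offspring = assign_fitness(offspring, cfg, rng)

    realized = parents.copy()
    counts = np.zeros(len(parents), dtype=int)
    np.add.at(counts, dams.loc[di, "index"].to_numpy(), 1)
    np.add.at(counts, sires.loc[si, "index"].to_numpy(), 1)
    realized["rs"] = counts
    return offspring, realized


def simulate_pedigree(cfg: SimConfig, return_latent: bool = False):
    """Simulate a full two-generation pedigree; deterministic given the seed.

    Returns a validated :class:`~tactqg.pedigree.Pedigree` (and, when
    ``return_latent`` is true, a side frame with the latent breeding
    values and environmental deviates keyed by id).
    """
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    founders = assign_fitness(founders, cfg, rng)
    offspring, founders = mate_and_breed(founders, cfg, rng)

    dam_ids = np.array([f"D{i + 1:05d}" for i in range(cfg.n_dams)])
    sire_ids = np.array([f"S{i + 1:05d}" for i in range(cfg.n_sires)])
    off_ids = np.array([f"O{i + 1:05d}" for i in range(cfg.n_offspring)])
    founder_ids = np.concatenate([dam_ids, sire_ids])

    par = founders.copy()
    par["id"] = founder_ids
    par["dam_id"] = pd.NA
    par["sire_id"] = pd.NA
    par["generation"] = "parent"

    off = offspring.copy()
    off["id"] = off_ids
    off["dam_id"] = dam_ids[off["dam_index"].to_numpy()]
    off["sire_id"] = sire_ids[off["sire_index"].to_numpy()]
    off["generation"] = "offspring"

    cols = ["id", "sex", "tactic", "year", "length_mm", "rs", "dam_id", "sire_id", "generation"]
    frame = pd.concat([par[cols], off[cols]], ignore_index=True)
    ped = Pedigree(frame, validate=True)
    if not return_latent:
        return ped
    latent_cols = ["id", "a_f", "a_h", "a_j", "a_l", "e"]
    latent = pd.concat([par[latent_cols], off[latent_cols]], ignore_index=True)
    return ped, latent
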