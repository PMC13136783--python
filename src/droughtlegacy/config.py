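"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class CovariateSpec:
    """AR(1) specification for one annual climate/vegetation covariate.

    ``mean`` and ``site_sd`` describe the between-site distribution of the
    site-level long-term mean; ``sd`` is the stationary within-site
    interannual standard deviation and ``ar1`` the lag-1 autocorrelation.
    """

    mean: float
    sd: float
    ar1: float
    site_sd: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.site_sd < 0:
            raise ValueError("covariate sd values must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")

    @property
    def marginal_sd(self) -> float:
        """Total (between + within site) standard deviation."""
        return float((self.sd**2 + self.site_sd**2) ** 0.5)


def default_covariates() -> dict[str, CovariateSpec]:
    """Default covariate processes: temperate-to-dryland flux-site climatology."""
    return {
        "t": CovariateSpec(10.0, 1.2, 0.4, 3.0),        # air temperature, degC
        "p": CovariateSpec(800.0, 120.0, 0.3, 200.0),   # precipitation, mm yr-1
        "srad": CovariateSpec(180.0, 12.0, 0.3, 25.0),  # shortwave radiation, W m-2
        "vpd": CovariateSpec(8.0, 1.2, 0.4, 2.5),       # vapour pressure deficit, hPa
        "sm": CovariateSpec(0.25, 0.03, 0.5, 0.05),     # soil moisture, m3 m-3
        "lai": CovariateSpec(3.0, 0.35, 0.5, 1.0),      # leaf area index
    }


@dataclass
class SimConfig:
    """Ground-truthed synthetic flux-site population.

    ``direct_effect`` is the fractional GPP change applied in drought years
    (-0.10 means a 10% loss); ``legacy_effect`` the fractional change in the
    first postdrought year, decaying linearly to zero after
    ``legacy_decay_years`` recovery years.  ``noise_cv`` is the coefficient
    of variation of the multiplicative lognormal observation noise.
    """

    n_sites: int = 200
    years_per_site: int = 30
    seed: int = 0
    direct_effect: float = -0.10
    legacy_effect: float = -0.05
    legacy_decay_years: int = 3
    noise_cv: float = 0.05
    drought_prob: float = 0.10
    site_log_sd: float = 0.10
    start_year: int = 1985
    cwd_reference_years: int = 40
    covariates: dict[str, CovariateSpec] = field(default_factory=default_covariates)

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.years_per_site < 8:
            raise ValueError("years_per_site must be >= 8")
        if not 0.0 < self.drought_prob < 1.0:
            raise ValueError("drought_prob must lie in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.legacy_decay_years < 0:
            raise ValueError("legacy_decay_years must be non-negative")
        if self.cwd_reference_years < 2:
            raise ValueError("cwd_reference_years must be >= 2")
        if self.site_log_sd < 0:
            raise ValueError("site_log_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        cov = d.pop("covariates", None)
        cfg = cls(**d)
        if cov is not None:
            cfg.covariates = {k: CovariateSpec(**v) if isinstance(v, dict) else v
                              for k, v in cov.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RFConfig:
    """Counterfactual random-forest settings."""

    n_trees: int = 500
    split_frac: float = 0.7
    seed: Optional[int] = None  # None -> derived from pipeline seed


@dataclass
class GAMConfig:
    """Driver-attribution additive-model settings."""

    alpha: float = 0.05
    spline_df: int = 5
    min_rows_per_term: int = 10


@dataclass
class PipelineConfig:
    """End-to-end analysis configuration; defaults reproduce the reference study setup.

    PDSI droughts are years strictly below ``pdsi_cut``; CWD droughts are
    years strictly above the site 95th-percentile climatic water deficit.
    Direct effects compare drought vs the three nearest predrought
    drought-free years; legacy effects compare up to four postdrought years
    against the expected no-drought GPP, with 1000 bootstrap resamples for
    95% confidence intervals.
    """

    metrics: tuple[str, ...] = ("PDSI", "CWD")
    pdsi_cut: float = -3.0
    cwd_quantile: float = 0.95
    pre_len: int = 3
    post_len: int = 4
    horizons: tuple[int, ...] = (1, 2, 3, 4)
    methods: tuple[str, ...] = ("baseline", "counterfactual")
    scales: tuple[str, ...] = ("absolute", "anomaly", "relative")
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    season_mode: str = "calendar"
    rf: RFConfig = field(default_factory=RFConfig)
    gam: GAMConfig = field(default_factory=GAMConfig)
    run_drivers: bool = True
    sim: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m not in ("PDSI", "CWD"):
                raise ValueError(f"unknown metric {m!r}")
        for m in self.methods:
            if m not in ("baseline", "counterfactual"):
                raise ValueError(f"unknown method {m!r}")
        for s in self.scales:
            if s not in ("absolute", "anomaly", "relative"):
                raise ValueError(f"unknown scale {s!r}")
        if self.season_mode not in ("calendar", "growing_season"):
            raise ValueError("season_mode must be 'calendar' or 'growing_season'")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.n_boot <= 0 or self.pre_len <= 0 or self.post_len <= 0:
            raise ValueError("n_boot, pre_len and post_len must be positive")
        if any(h < 1 or h > self.post_len for h in self.horizons):
            raise ValueError("horizons must lie in 1..post_len")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("rf"), dict):
            d["rf"] = RFConfig(**d["rf"])
        if isinstance(d.get("gam"), dict):
            d["gam"] = GAMConfig(**d["gam"])
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("metrics", "horizons", "methods", "scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
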