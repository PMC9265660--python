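"""Synthetic panels with the structure the three-stage method assumes.

The generator builds a known production frontier and then inflates inputs by
three additive components per input: an environment effect Z*beta, a
half-normal management inefficiency u, and Gaussian noise v — exactly the
data-generating assumption behind the Stage-2 slack regressions. Components
are drawn on a fixed per-input scale (a fraction of the input's typical
frontier level), so the slack regression S = Z beta + v + u is literally the
generating model, and

    X = X_frontier + f_true + u_true + v_true     (exactly, u_true >= 0)

always reconstructs the observed inputs.

Defaults emulate the panel the method was designed for: 13 units x 20 years,
4 inputs, 1 desirable output (also the weighting basis), 1 undesirable
output scaling with production, and 5 cross-correlated environmental
covariates. Units are near-homogeneous in scale — the additive Stage-2
leveling is not translation-invariant under constant returns, so, like the
provinces the approach is applied to, comparable unit sizes are a stated
assumption, not an accident. The environment is predominantly transient
(year-to-year variation within units): with 13 units and 5 covariates a
persistent environment cannot be separated from persistent management by
any regression, whereas transient variation identifies the slack
coefficients from all J*T observations. Effect sizes are calibrated once so
that the stage-1 efficiency spread across units is roughly 0.3-0.4 (the
dispersion typical of provincial efficiency tables), gamma =
sigma_u^2/(sigma_u^2 + sigma_v^2) is close to 1 (management dominates noise,
the usual finding in slack regressions), and clipping at the input floor
stays below 1% of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PanelDataset

__all__ = ["SimulationConfig", "GroundTruth", "generate_panel", "toy_fixture"]


def _default_beta_env(m, p, scale=0.22):
    """Environment coefficients (relative to each input's typical level).

    The sign pattern is shared across inputs — the radial part of a DEA input
    gap is common to all inputs, so covariates whose effect flips sign from
    one input to the next cannot be disentangled by slack regressions; a
    shared pattern with input-specific magnitudes is the regime in which the
    three-stage adjustment is identified.
    """
    base = np.resize(np.array([1.0, -0.5, 0.75, -0.25, 0.5]), p)
    mags = np.linspace(1.0, 0.6, m)
    return scale * np.outer(mags, base)


@dataclass
class SimulationConfig:
    """Stated world for the generator; every field has a recorded default."""

    J: int = 13                 # units
    T: int = 20                 # periods
    m: int = 4                  # inputs
    p: int = 5                  # environmental covariates
    seed: int = 0
    beta_env: np.ndarray | None = None   # (m, p), relative to input scale
    sigma_u: float = 0.55       # half-normal management inefficiency (relative)
    sigma_v: float = 0.02       # noise (relative); gamma ~ 1 as in slack SFAs
    u_persistence: float = 0.9  # Gaussian-copula correlation of u over time
    u_input_corr: float = 0.85  # copula correlation of u across inputs
    tfp_trend: float = 1.02     # frontier input requirement shrinks 2%/yr
    rts_exponent: float = 1.0   # constant returns on the true frontier
    carbon_rate: float = 0.1    # undesirable output per unit desirable output
    weight_profile: float = 0.03  # sd of log unit output scales
    env_unit_sd: float = 0.15   # persistent unit component of Z
    env_noise_sd: float = 1.3   # transient component of Z
    env_common_load: float = 0.5  # loading on the shared factor across covariates
    floor: float = 0.05         # X >= floor * frontier input

    def __post_init__(self):
        if self.J < 3 or self.T < 2:
            raise ValueError("need J >= 3 units and T >= 2 periods")
        if min(self.sigma_u, self.sigma_v) < 0 or self.tfp_trend <= 0:
            raise ValueError("scales must be nonnegative, trend positive")
        if self.beta_env is None:
            self.beta_env = _default_beta_env(self.m, self.p)
        self.beta_env = np.asarray(self.beta_env, dtype=float).reshape(
            self.m, self.p)


@dataclass
class GroundTruth:
    efficient_inputs: np.ndarray   # (J, T, m) frontier-minimal inputs
    f_true: np.ndarray             # (J, T, m) environment component (additive)
    u_true: np.ndarray             # (J, T, m) management inefficiency, >= 0
    v_true: np.ndarray             # (J, T, m) noise (clipping absorbed here)
    true_efficiency: np.ndarray    # (J, T) management-only efficiency
    true_beta: np.ndarray          # (m, p) generator coefficients
    env_advantage: np.ndarray      # (J,) mean relative environment relief
    n_clipped: int = 0

    def observed_inputs(self):
        return self.efficient_inputs + self.f_true + self.u_true + self.v_true


def generate_panel(cfg: SimulationConfig):
    """Draw one panel and its ground truth, reproducibly from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    J, T, m, p = cfg.J, cfg.T, cfg.m, cfg.p

    # heterogeneous unit sizes and a gently growing desirable output
    scale = np.exp(rng.normal(0.0, cfg.weight_profile, size=J))
    growth = 1.0 + rng.normal(0.01, 0.001, size=J)
    t_grid = np.arange(T)
    Y = scale[:, None] * np.power.outer(growth, t_grid)          # (J, T)
    Y *= np.exp(rng.normal(0.0, 0.01, size=(J, T)))              # output noise

    # frontier input requirement per input, shifting in by tfp_trend each year
    a = np.linspace(0.6, 1.4, m)
    trend = cfg.tfp_trend ** t_grid
    x_star = a[None, None, :] * (Y ** cfg.rts_exponent)[:, :, None] \
        / trend[None, :, None]

    # environmental covariates: persistent unit component with a shared
    # factor across covariates, plus transient noise
    common = rng.normal(0.0, 1.0, size=J)
    zeta = (cfg.env_common_load * common[:, None]
            + np.sqrt(max(1 - cfg.env_common_load ** 2, 0.0))
            * rng.normal(0.0, 1.0, size=(J, p))) * cfg.env_unit_sd
    Z = zeta[:, None, :] + rng.normal(0.0, cfg.env_noise_sd, size=(J, T, p))

    # additive slack components, drawn on a fixed per-input scale so the
    # Stage-2 regression S = Z beta + v + u is exactly the generating model
    x_scale = x_star.mean(axis=(0, 1))                   # (m,) typical levels
    f_true = np.einsum("jtp,ip->jti", Z, cfg.beta_env) * x_scale

    # half-normal u via a Gaussian copula: a scalar management factor per
    # unit-year (mildly persistent over time) drives waste of all inputs
    # together, plus input-specific idiosyncrasies; the folded variable
    # remains marginally half-normal
    rho_t, rho_x = cfg.u_persistence, cfg.u_input_corr
    core = rng.normal(0.0, 1.0, size=(J, 1))
    mgmt = rho_t * core + np.sqrt(max(1 - rho_t ** 2, 0.0)) * \
        rng.normal(0.0, 1.0, size=(J, T))
    g = rho_x * mgmt[:, :, None] + np.sqrt(max(1 - rho_x ** 2, 0.0)) * \
        rng.normal(0.0, 1.0, size=(J, T, m))
    u_true = np.abs(g) * cfg.sigma_u * x_scale
    v_true = rng.normal(0.0, cfg.sigma_v, size=(J, T, m)) * x_scale

    X = x_star + f_true + u_true + v_true
    lower = cfg.floor * x_star
    clipped = X < lower
    n_clipped = int(clipped.sum())
    X = np.maximum(X, lower)
    if np.any(X <= 0):
        raise ValueError("configuration produced nonpositive inputs; "
                         "rescale sigma/beta or raise the floor")
    # clipping (rare by calibration) is absorbed into the noise component so
    # the additive reconstruction stays exact
    v_true = X - x_star - f_true - u_true

    u_rel = u_true / x_scale
    true_eff = 1.0 / (1.0 + u_rel.mean(axis=2))          # management only
    env_adv = -(f_true / x_scale).mean(axis=(1, 2))      # relief = low f

    # emissions are a joint product of output whose intensity falls with the
    # technology trend; exact proportionality to output would make the bad
    # constraint collide with the output constraint in as-input scoring
    B = cfg.carbon_rate * Y[:, :, None] / trend[None, :, None]
    B = B * np.exp(rng.normal(0.0, 0.01, size=B.shape))

    data = PanelDataset(
        dmu_ids=[f"U{j+1:02d}" for j in range(J)],
        periods=list(range(2000, 2000 + T)),
        X=X, Y=Y[:, :, None], B=B, Z=Z, W=Y,
        input_names=[f"x{i+1}" for i in range(m)],
        output_names=["y"], bad_names=["carbon"],
        env_names=[f"z{k+1}" for k in range(p)], weight_name="y",
    )
    truth = GroundTruth(
        efficient_inputs=x_star, f_true=f_true, u_true=u_true, v_true=v_true,
        true_efficiency=true_eff, true_beta=cfg.beta_env.copy(),
        env_advantage=env_adv, n_clipped=n_clipped,
    )
    return data, truth


def toy_fixture() -> PanelDataset:
    """Fixed 4-unit x 2-period panel with hand-solvable radial efficiencies.

    Single input, single output, undesirable output proportional to the input
    (so folding it in as an input leaves radial scores unchanged). Output per
    input: A = 2 (frontier), B = 1, C = 0.5, D = 0.5, hence CRS radial scores
    1.0, 0.5, 0.25, 0.25 in both (identical) periods.
    """
    x = np.array([2.0, 4.0, 4.0, 8.0])
    y = np.array([4.0, 4.0, 2.0, 4.0])
    X = np.stack([x, x], axis=1)[:, :, None]
    Y = np.stack([y, y], axis=1)[:, :, None]
    B = 0.5 * X.copy()
    W = Y[:, :, 0]
    return PanelDataset(
        dmu_ids=["A", "B", "C", "D"], periods=[2000, 2001],
        X=X, Y=Y, B=B, Z=np.zeros((4, 2, 0)), W=W,
        input_names=["x"], output_names=["y"], bad_names=["carbon"],
        env_names=[], weight_name="y",
    )
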