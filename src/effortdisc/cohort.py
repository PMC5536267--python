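"""Synthetic EDQ cohort generator.

Generates agents with known ("ground-truth") discounting parameters and
simulates their questionnaire choices, so that every pipeline stage —
extraction, fitting, selection, the comparison suite — is testable end to
end without any empirical data.

The generative structure mirrors the statistical regularities the analysis
is designed to detect:

* per reward magnitude, l and s are log-normal (positively skewed);
* the magnitude effect is built in: within each agent and domain, l strictly
  decreases and s strictly increases with the reward amount (ordered medians
  scaled by a shared agent-level multiplier, which preserves the ordering
  for every draw);
* physical and cognitive parameters correlate positively through a shared
  standard-normal latent mixed with weight sqrt(rho);
* each condition receives a single noisy valuation V = SV + eps with
  eps ~ N(0, (sigma A)²), truncated to the ladder's range [0, A]; the agent
  then chooses the effortless alternative on every row whose amount is >= V
  and the effortful one below, guaranteeing the single-switch pattern the
  EDQ stop rule enforces behaviourally.  Zero-effort (delay-only) pages get
  V = A: no discounting at E = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, build_ladder, enumerate_conditions
from .models import get_model, sv

__all__ = ["AgentTruth", "CohortConfig", "sample_agent", "simulate_choices",
           "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative settings.

    Medians are per reward magnitude, parallel to ``DesignSpec.amounts``.
    The defaults encode visible, magnitude-dependent discounting for a
    median agent: devaluation of roughly 40%/25%/12% of A at the highest
    effort level for the small/medium/large amounts (the magnitude effect:
    proportionally less discounting for larger rewards), with curvature s
    rising from mildly concave to strongly concave as the amount grows.
    The log-normal spreads are set so that most agents show graded partial
    discounting while the tails contain a minority of non-discounters and
    full (floor) discounters.  ``noise_sigma`` is the valuation noise SD as
    a fraction of A.
    """

    seed: int
    n_agents: int = 114
    true_model: str = "power"
    l_medians: tuple[float, ...] = (7.8e-2, 1.21e-2, 2.9e-4)
    s_medians: tuple[float, ...] = (1.2, 1.8, 2.8)
    log_sd_l: float = 0.55
    log_sd_s: float = 0.08
    rho_l: float = 0.5
    rho_s: float = 0.45
    noise_sigma: float = 0.03

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_agents < 0:
            raise ValueError("n_agents must be >= 0")
        for name in ("log_sd_l", "log_sd_s", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_l", "rho_s"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        for key in ("l_medians", "s_medians"):
            if key in data:
                data = {**data, key: tuple(data[key])}
        return cls(**data)


@dataclass
class AgentTruth:
    """Ground-truth parameters of one simulated participant."""

    participant_id: str
    model: str
    #: (domain, amount) -> {"l": float, "s": float}
    params: dict
    noise_sigma: float

    def rows(self) -> list[dict]:
        return [{"participant_id": self.participant_id, "model": self.model,
                 "domain": domain, "amount": amount,
                 "l_true": pars["l"], "s_true": pars["s"],
                 "noise_sigma": self.noise_sigma}
                for (domain, amount), pars in self.params.items()]


def sample_agent(config: CohortConfig, rng: np.random.Generator,
                 participant_id: str = "P001",
                 spec: DesignSpec | None = None) -> AgentTruth:
    """Draw one agent's parameters from the cohort distribution."""
    spec = spec or DesignSpec()
    if len(config.l_medians) != len(spec.amounts):
        raise ValueError("l_medians must parallel the design amounts")
    z_l, z_s = rng.standard_normal(2)  # cross-domain latents
    params = {}
    for domain in spec.effort_domains:
        eta_l, eta_s = rng.standard_normal(2)
        g_l = math.sqrt(config.rho_l) * z_l + math.sqrt(1 - config.rho_l) * eta_l
        g_s = math.sqrt(config.rho_s) * z_s + math.sqrt(1 - config.rho_s) * eta_s
        mult_l = math.exp(config.log_sd_l * g_l)
        mult_s = math.exp(config.log_sd_s * g_s)
        for amount, l_med, s_med in zip(spec.amounts, config.l_medians,
                                        config.s_medians):
            params[(domain, amount)] = {"l": l_med * mult_l,
                                        "s": s_med * mult_s}
    return AgentTruth(participant_id, config.true_model, params,
                      config.noise_sigma)


def agent_valuations(agent: AgentTruth, spec: DesignSpec,
                     rng: np.random.Generator | None = None) -> dict:
    """Noisy valuation V per condition page (keyed like ``agent.params``
    plus the effort level).  With ``rng=None`` the valuations are noiseless.

    V is truncated to [0, A]: the ladder cannot record valuations outside
    its range.
    """
    model = get_model(agent.model)
    out = {}
    for cond in enumerate_conditions(spec, include_zero_effort=True):
        A = cond.amount
        if cond.is_zero_effort:
            out[(cond.domain, A, 0)] = float(A)
            continue
        pars = agent.params[(cond.domain, A)]
        s = pars["s"] if model.n_params == 2 else None
        value = float(sv(model, A, cond.effort_level, pars["l"], s))
        if rng is not None and agent.noise_sigma > 0:
            value += rng.normal(0.0, agent.noise_sigma * A)
        out[(cond.domain, A, cond.effort_level)] = float(np.clip(value, 0.0, A))
    return out


def simulate_choices(agent: AgentTruth, spec: DesignSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one agent's full questionnaire.

    One valuation draw per condition (not per row) keeps every page
    single-switch.  Pages are emitted in a per-agent random order
    (counterbalancing); the procedure stops at the switch row, as on paper.
    """
    valuations = agent_valuations(agent, spec, rng)
    conditions = enumerate_conditions(spec, include_zero_effort=True)
    order = rng.permutation(len(conditions))
    rows = []
    for idx in order:
        cond = conditions[idx]
        ladder = build_ladder(cond.amount, spec)
        v = valuations[(cond.domain, cond.amount, cond.effort_level)]
        for row_index, offered in enumerate(ladder.rows, start=1):
            choice = "effortless" if offered >= v else "effortful"
            rows.append({"participant_id": agent.participant_id,
                         "domain": cond.domain, "amount": cond.amount,
                         "effort_level": cond.effort_level,
                         "row_index": row_index,
                         "effortless_value": offered, "choice": choice})
            if choice == "effortful":
                break  # stop-at-switch, as in the procedure
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig,
                    spec: DesignSpec | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (agents, choices) tables for a full cohort.

    Deterministic for a given ``config.seed``.  The agents table is the
    ground truth against which parameter recovery is scored.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(config.seed)
    agent_rows, choice_frames = [], []
    width = max(3, len(str(max(config.n_agents, 1))))
    for i in range(config.n_agents):
        pid = f"P{i + 1:0{width}d}"
        agent = sample_agent(config, rng, pid, spec)
        agent_rows.extend(agent.rows())
        choice_frames.append(simulate_choices(agent, spec, rng))
    agents = pd.DataFrame(agent_rows, columns=[
        "participant_id", "model", "domain", "amount", "l_true", "s_true",
        "noise_sigma"])
    if choice_frames:
        choices = pd.concat(choice_frames, ignore_index=True)
    else:
        choices = pd.DataFrame(columns=[
            "participant_id", "domain", "amount", "effort_level",
            "row_index", "effortless_value", "choice"])
    return agents, choices
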