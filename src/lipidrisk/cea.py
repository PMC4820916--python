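"""Decision-analytic cost-effectiveness of screening-and-intervention strategies.

Seven one-time screening strategies for 5-year diabetes prevention are
compared from a single-payer perspective: no screening; fasting plasma
glucose (FPG) followed by lifestyle intervention or by metformin for the
high-risk group; lipidomic-risk-score (LRS) screening followed by
metformin or by lifestyle intervention; FPG and LRS combined; and
risk-factor questionnaire combined with LRS.  Each strategy maps
subjects into high/moderate/low risk groups, assigns an intervention per
group, and leads to a chance node for incident diabetes within five
years with probability p_group * (1 - efficacy).  Terminal payoffs carry
the accumulated screening + intervention + medical costs and 5-year
QALYs.  Strategies are evaluated by rolling back the decision tree;
outputs are expected cost, expected QALYs, expected risk reduction,
incremental cost-effectiveness ratios (ICER) against a reference
strategy, and net monetary benefit (NMB = WTP * QALY - cost) at a
willingness-to-pay of US$ 4450.12 per 5-year prevention program (2015
US$).  Costs and QALYs are undiscounted.  Sensitivity is explored with
one-way tornado scans and a microsimulation whose per-strategy expected
values are smoothed with a fourth-order polynomial.

The default cost/utility tables are a documented reconstruction on the
scale of published Diabetes Prevention Program (DPP) economics; every
number is overridable through :class:`CeaInputs`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Screening-test component costs (2015 US$).
DEFAULT_SCREEN_COSTS = {
    "lrs_assay": 11.0,       # ~1 $/species x 3 + 4 $ mass spec + 4 $ manpower
    "sample_prep": 29.0,     # charged once per strategy
    "primary_care_visit": 50.0,  # charged once per strategy
    "fpg": 9.0,              # reconstructed default, overridable
    "risk_factor_questionnaire": 2.0,  # reconstructed default, overridable
}

#: Intervention efficacies (relative reduction in 5-year T2D probability).
DEFAULT_EFFICACY = {"lifestyle": 0.58, "metformin": 0.31, "none": 0.0}


def lrs_assay_cost(
    n_species: int = 3,
    cost_per_species: float = 1.0,
    mass_spec_cost: float = 4.0,
    manpower_cost: float = 4.0,
) -> float:
    """Per-assay cost of the three-species lipidomic score (2015 US$).

    Assembled from its components: ~1 $ per lipid species measured in a
    high-throughput facility, ~4 $ of mass-spectrometry time and 4 $ of
    manpower, totalling 11 $ for the three-species assay.
    """
    return n_species * cost_per_species + mass_spec_cost + manpower_cost


@dataclass
class StrategySpec:
    """A screening-and-intervention strategy.

    ``tests`` are (name, per-test cost) pairs; sample-preparation and
    primary-care-visit costs are shared and charged exactly once per
    strategy regardless of how many assays it uses.  ``risk_groups`` maps
    group name -> probability of assignment; ``interventions`` maps group
    name -> intervention name.
    """

    name: str
    tests: list = field(default_factory=list)
    shared_costs: float = 0.0
    risk_groups: dict = field(default_factory=lambda: {"LR": 1.0})
    interventions: dict = field(default_factory=lambda: {"LR": "none"})

    def __post_init__(self):
        total = sum(self.risk_groups.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"risk-group probabilities sum to {total}, not 1")
        for g in self.risk_groups:
            if g not in self.interventions:
                raise ValueError(f"no intervention for risk group {g!r}")

    @property
    def screening_cost(self) -> float:
        return sum(c for _, c in self.tests) + self.shared_costs


@dataclass
class CeaInputs:
    """Probabilities, costs and utilities feeding the decision tree.

    ``p_t2d_5y`` is the untreated 5-year diabetes probability per risk
    group; ``qaly_5y`` maps (t2d_status, intervention) to 5-year QALYs;
    ``medical_cost_5y`` maps diabetes status to 5-year medical costs;
    ``intervention_cost_5y`` the 5-year program cost per intervention.
    Default values are reconstructed on the scale of published DPP
    economics (2015 US$, undiscounted) and fully overridable.
    """

    p_t2d_5y: dict = field(
        default_factory=lambda: {"HR": 0.35, "MR": 0.15, "LR": 0.04, "ALL": 0.143}
    )
    efficacy: dict = field(default_factory=lambda: dict(DEFAULT_EFFICACY))
    intervention_cost_5y: dict = field(
        default_factory=lambda: {"lifestyle": 2780.0, "metformin": 270.0, "none": 0.0}
    )
    medical_cost_5y: dict = field(default_factory=lambda: {True: 13700.0, False: 3600.0})
    qaly_5y: dict = field(
        default_factory=lambda: {
            (False, "lifestyle"): 4.56,
            (False, "metformin"): 4.52,
            (False, "none"): 4.50,
            (True, "lifestyle"): 4.16,
            (True, "metformin"): 4.13,
            (True, "none"): 4.10,
        }
    )
    wtp: float = 4450.12

    def __post_init__(self):
        for g, p in self.p_t2d_5y.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_t2d_5y[{g!r}] outside [0, 1]")
        for k, e in self.efficacy.items():
            if not 0 <= e <= 1:
                raise ValueError(f"efficacy[{k!r}] outside [0, 1]")
        for d in (self.intervention_cost_5y, self.medical_cost_5y):
            for k, c in d.items():
                if c < 0:
                    raise ValueError(f"negative cost for {k!r}")

    @staticmethod
    def _coerce_key(target: dict, raw: str):
        """Resolve a dotted-path dict key; supports bools and tuple keys
        written as 'True,lifestyle'."""
        if raw in target:
            return raw
        parts = [
            p == "True" if p in ("True", "False") else p for p in raw.split(",")
        ]
        key = parts[0] if len(parts) == 1 else tuple(parts)
        if key not in target:
            raise KeyError(f"unknown parameter key {raw!r}")
        return key

    def with_parameter(self, path: str, value) -> "CeaInputs":
        """Clone with one dotted parameter replaced, e.g. 'p_t2d_5y.HR'."""
        new = copy.deepcopy(self)
        parts = path.split(".", 1)
        if len(parts) == 1:
            setattr(new, parts[0], value)
        else:
            target = getattr(new, parts[0])
            target[self._coerce_key(target, parts[1])] = value
        return new

    def get_parameter(self, path: str):
        parts = path.split(".", 1)
        target = getattr(self, parts[0])
        if len(parts) == 1:
            return target
        return target[self._coerce_key(target, parts[1])]


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """Decision-tree node: a chance node with (probability, child) branches
    or a leaf with a payoff dict {'cost', 'qaly', 't2d'}."""

    kind: str  # 'chance' | 'leaf'
    branches: list = field(default_factory=list)  # [(p, Node), ...]
    payoff: dict = field(default_factory=dict)
    label: str = ""


def rollback(node: Node) -> dict:
    """Expected payoffs by backward induction.

    Raises on chance nodes whose branch probabilities do not sum to 1.
    """
    if node.kind == "leaf":
        return dict(node.payoff)
    total = sum(p for p, _ in node.branches)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"unnormalized chance node {node.label!r}: sum={total}")
    agg: dict = {}
    for p, child in node.branches:
        sub = rollback(child)
        for k, v in sub.items():
            agg[k] = agg.get(k, 0.0) + p * v
    return agg


def build_tree(strategy: StrategySpec, inputs: CeaInputs) -> Node:
    """Instantiate a strategy's tree: risk groups -> intervention -> T2D."""
    screen = strategy.screening_cost
    group_branches = []
    for g, pg in strategy.risk_groups.items():
        interv = strategy.interventions[g]
        p_base = inputs.p_t2d_5y[g]
        eff = inputs.efficacy[interv]
        p_t2d = p_base * (1 - eff)
        c_fixed = screen + inputs.intervention_cost_5y[interv]
        branches = []
        for status, p_status in ((True, p_t2d), (False, 1 - p_t2d)):
            leaf = Node(
                kind="leaf",
                payoff={
                    "cost": c_fixed + inputs.medical_cost_5y[status],
                    "qaly": inputs.qaly_5y[(status, interv)],
                    "t2d": 1.0 if status else 0.0,
                },
                label=f"{g}/{interv}/{'T2D' if status else 'noT2D'}",
            )
            branches.append((p_status, leaf))
        group_branches.append((pg, Node(kind="chance", branches=branches, label=g)))
    return Node(kind="chance", branches=group_branches, label=strategy.name)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------


def build_default_strategies(
    risk_distributions: dict,
    screen_costs: dict | None = None,
) -> list:
    """Instantiate the seven candidate strategies.

    Parameters
    ----------
    risk_distributions : dict
        Risk-group probabilities per screening method, keys ``"fpg"``,
        ``"lrs"``, ``"fpg_lrs"``, ``"rf_lrs"``; each a dict over
        HR/MR/LR summing to 1 (MR optional).
    screen_costs : dict, optional
        Overrides for :data:`DEFAULT_SCREEN_COSTS`.

    Strategies containing an LRS assay carry the once-only shared
    sample-preparation and primary-care-visit costs in addition to the
    per-assay cost; combined strategies charge the shared costs exactly
    once, never per assay.  The no-screening arm applies the
    population-average 5-year risk (group ``"ALL"``).
    """
    c = dict(DEFAULT_SCREEN_COSTS)
    if screen_costs:
        c.update(screen_costs)
    shared = c["sample_prep"] + c["primary_care_visit"]
    d = risk_distributions

    def interv(groups, hr, mr="none"):
        out = {}
        for g in groups:
            out[g] = hr if g == "HR" else (mr if g == "MR" else "none")
        return out

    strategies = [
        StrategySpec(
            name="1. No screening",
            tests=[], shared_costs=0.0,
            risk_groups={"ALL": 1.0}, interventions={"ALL": "none"},
        ),
        StrategySpec(
            name="2. FPG -> lifestyle (IFG)",
            tests=[("fpg", c["fpg"])], shared_costs=0.0,
            risk_groups=dict(d["fpg"]),
            interventions=interv(d["fpg"], "lifestyle"),
        ),
        StrategySpec(
            name="3. LRS -> metformin (high score)",
            tests=[("lrs", c["lrs_assay"])], shared_costs=shared,
            risk_groups=dict(d["lrs"]),
            interventions=interv(d["lrs"], "metformin"),
        ),
        StrategySpec(
            name="4. LRS -> lifestyle (high score)",
            tests=[("lrs", c["lrs_assay"])], shared_costs=shared,
            risk_groups=dict(d["lrs"]),
            interventions=interv(d["lrs"], "lifestyle"),
        ),
        StrategySpec(
            name="5. FPG -> metformin (IFG)",
            tests=[("fpg", c["fpg"])], shared_costs=0.0,
            risk_groups=dict(d["fpg"]),
            interventions=interv(d["fpg"], "metformin"),
        ),
        StrategySpec(
            name="6. FPG + LRS -> lifestyle (HR) / metformin (MR)",
            tests=[("fpg", c["fpg"]), ("lrs", c["lrs_assay"])], shared_costs=shared,
            risk_groups=dict(d["fpg_lrs"]),
            interventions=interv(d["fpg_lrs"], "lifestyle", mr="metformin"),
        ),
        StrategySpec(
            name="7. RF + LRS -> lifestyle (HR) / metformin (MR)",
            tests=[("rf", c["risk_factor_questionnaire"]), ("lrs", c["lrs_assay"])],
            shared_costs=shared,
            risk_groups=dict(d["rf_lrs"]),
            interventions=interv(d["rf_lrs"], "lifestyle", mr="metformin"),
        ),
    ]
    return strategies


def evaluate_strategies(strategies, inputs: CeaInputs) -> pd.DataFrame:
    """Roll back every strategy; adds risk reduction vs no intervention."""
    rows = []
    for s in strategies:
        ev = rollback(build_tree(s, inputs))
        baseline_risk = sum(p * inputs.p_t2d_5y[g] for g, p in s.risk_groups.items())
        rows.append(
            {
                "strategy": s.name,
                "cost": ev["cost"],
                "qaly": ev["qaly"],
                "t2d_risk": ev["t2d"],
                "risk_reduction": baseline_risk - ev["t2d"],
            }
        )
    return pd.DataFrame(rows).set_index("strategy")


def icer_nmb(results: pd.DataFrame, reference: str, wtp: float) -> pd.DataFrame:
    """ICER vs a reference strategy, NMB and dominance flags.

    ICER = (cost - cost_ref) / (qaly - qaly_ref); flagged undefined when
    incremental QALYs are <= 0.  A strategy is dominated when it costs
    more and yields no more QALYs than the reference.
    NMB = wtp * qaly - cost.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 strategies")
    if reference not in results.index:
        raise KeyError(f"reference strategy {reference!r} not in results")
    ref = results.loc[reference]
    out = results.copy()
    d_cost = out["cost"] - ref["cost"]
    d_qaly = out["qaly"] - ref["qaly"]
    icer = np.where(d_qaly > 0, d_cost / d_qaly, np.nan)
    out["delta_cost"] = d_cost
    out["delta_qaly"] = d_qaly
    out["icer"] = icer
    out["icer_defined"] = d_qaly > 0
    out.loc[reference, "icer_defined"] = False
    out["dominated"] = (d_qaly <= 0) & (d_cost >= 0) & (out.index != reference)
    out["nmb"] = wtp * out["qaly"] - out["cost"]
    return out


def tornado(strategies, inputs: CeaInputs, parameter_ranges: dict,
            strategy_name: str = None, wtp: float = None) -> pd.DataFrame:
    """One-way sensitivity scan: EV at each parameter-range endpoint.

    EV is the NMB of ``strategy_name`` (or the best NMB across strategies
    when None), all other parameters at base case.  Ranges must bracket
    the base value.  Rows are sorted by absolute EV swing.
    """
    wtp = inputs.wtp if wtp is None else wtp

    def ev(inp):
        res = evaluate_strategies(strategies, inp)
        nmb = wtp * res["qaly"] - res["cost"]
        return float(nmb[strategy_name]) if strategy_name else float(nmb.max())

    base_ev = ev(inputs)
    rows = []
    for param, (lo, hi) in parameter_ranges.items():
        base = inputs.get_parameter(param)
        if not (lo <= base <= hi):
            raise ValueError(f"range for {param!r} does not bracket base value {base}")
        ev_lo = ev(inputs.with_parameter(param, lo))
        ev_hi = ev(inputs.with_parameter(param, hi))
        rows.append(
            {
                "parameter": param,
                "base": base,
                "ev_base": base_ev,
                "ev_low": ev_lo,
                "ev_high": ev_hi,
                "swing": abs(ev_hi - ev_lo),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False)
        .reset_index(drop=True)
    )


def one_way_microsim(
    strategies,
    inputs: CeaInputs,
    parameter: str,
    prange: tuple,
    n_runs: int = 1000,
    seed: int = 0,
    poly_degree: int = 4,
) -> dict:
    """Microsimulation over one parameter with polynomial smoothing.

    The parameter is drawn uniformly over ``prange`` for each run; every
    strategy's tree is rolled back per run.  Per strategy, the expected
    cost/QALY ratio versus the sampled parameter is smoothed by
    least-squares polynomial regression of degree ``poly_degree``.

    Returns {strategy: {'param', 'cost', 'qaly', 'ev', 'poly', 'fitted'}}.
    """
    if n_runs < 10:
        raise ValueError("use at least 10 microsimulation runs")
    rng = np.random.default_rng(seed)
    lo, hi = prange
    samples = rng.uniform(lo, hi, n_runs)
    out = {}
    records = {s.name: {"cost": [], "qaly": []} for s in strategies}
    for x in samples:
        inp = inputs.with_parameter(parameter, float(x))
        for s in strategies:
            ev = rollback(build_tree(s, inp))
            records[s.name]["cost"].append(ev["cost"])
            records[s.name]["qaly"].append(ev["qaly"])
    for s in strategies:
        cost = np.asarray(records[s.name]["cost"])
        qaly = np.asarray(records[s.name]["qaly"])
        ev = cost / qaly
        coeffs = np.polyfit(samples, ev, poly_degree)
        out[s.name] = {
            "param": samples,
            "cost": cost,
            "qaly": qaly,
            "ev": ev,
            "poly": coeffs,
            "fitted": np.polyval(coeffs, samples),
        }
    return out
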