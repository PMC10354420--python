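"""End-to-end orchestration: meta-analysis -> microsimulation -> Markov
cohort model -> one-way and probabilistic sensitivity analysis.

The pipeline's moving parts meet in :func:`make_evaluator`, which closes a
flat parameter vector (state costs and utilities, stage mortalities, per-arm
transition probabilities, hemodialysis fraction, drug dosing, discount rate)
over the two-strategy comparison and returns a :class:`~ckd_cea.markov.CEResult`.
The same evaluator serves the base case, the tornado analysis and the PSA,
so all three are guaranteed to agree at base values.

Every stochastic stage draws its seed from one ``numpy.random.SeedSequence``
spawned off the run seed, recorded in the run manifest; result files contain
no timestamps, so re-running a manifest reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .markov import (
    ModelConfig,
    Payoffs,
    Strategy,
    annual_drug_cost,
    build_matrix,
    compare,
    evaluate_strategy,
)
from .egfr import StagingRule
from .meta import (
    COVARIATE_NAMES,
    EffectPooler,
    TrialRecord,
    forest_table,
    meta_regress,
    read_trials_csv,
)
from .microsim import ArmEffect, CohortSpec, estimate_transitions, sample_cohort
from .sensitivity import ParamSpec, ceac, one_way_sa, run_psa

__all__ = [
    "load_config",
    "save_config",
    "make_evaluator",
    "build_param_specs",
    "estimate_arm_transitions",
    "run_pipeline",
    "PipelineResult",
    "RunManifest",
]

logger = logging.getLogger(__name__)

_STATE_KEYS = ("ckd3", "ckd4", "ckd5_nohd", "ckd5_hd")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def base_param_values(config: dict, transitions: Mapping[str, float]) -> dict:
    """Flatten the config + estimated transitions into the parameter vector."""
    values = {}
    for s in _STATE_KEYS:
        values[f"cost_{s}"] = float(config["placeholder_costs"][s])
        values[f"util_{s}"] = float(config["placeholder_utilities"][s])
        values[f"mort_{s}"] = float(config["placeholder_mortality"][s])
    for k in ("p_3to4_ctl", "p_4to5_ctl", "p_3to4_trt", "p_4to5_trt"):
        values[k] = float(transitions[k])
    values["hd_fraction"] = float(config["model"]["hd_fraction"])
    values["drug_daily_tablets"] = float(config["drug"]["daily_tablets"])
    values["drug_compliance"] = float(config["drug"]["compliance"])
    values["discount_rate"] = float(config["model"]["discount_rate"])
    return values


def make_evaluator(config: dict) -> Callable[[Mapping[str, float]], "object"]:
    """Close the two-strategy Markov comparison over a parameter vector.

    The returned callable maps a flat {name: value} dict (see
    :func:`base_param_values`) to a :class:`~ckd_cea.markov.CEResult` for
    the combined-treatment strategy vs the standard-care strategy.
    """
    model_cfg = config["model"]
    drug_cfg = config["drug"]
    cost_states = tuple(drug_cfg.get("cost_states", ("ckd3", "ckd4")))

    def evaluator(values: Mapping[str, float]):
        cfg = ModelConfig(
            horizon=int(model_cfg["horizon"]),
            cycle_years=float(model_cfg.get("cycle_years", 1.0)),
            discount_rate=float(values["discount_rate"]),
            hd_fraction=float(values["hd_fraction"]),
            wtp=float(model_cfg["wtp"]),
            half_cycle=bool(model_cfg.get("half_cycle", True)),
            ordering=model_cfg.get("ordering", "death_first"),
        )
        mortality = {s: values[f"mort_{s}"] for s in _STATE_KEYS}
        payoffs_ctl = Payoffs(
            costs={s: values[f"cost_{s}"] for s in _STATE_KEYS},
            utilities={s: values[f"util_{s}"] for s in _STATE_KEYS},
        )
        drug_cost = annual_drug_cost(
            unit_price=float(drug_cfg["pack_price"]),
            tablets_per_pack=int(drug_cfg["tablets_per_pack"]),
            daily_tablets=float(values["drug_daily_tablets"]),
            compliance=float(values["drug_compliance"]),
            days=float(drug_cfg.get("days_per_cycle", 365)),
        )
        payoffs_trt = payoffs_ctl.with_extra_cost(
            {s: drug_cost for s in cost_states}
        )
        m_ctl = build_matrix(values["p_3to4_ctl"], values["p_4to5_ctl"],
                             mortality, cfg.hd_fraction, cfg.ordering)
        m_trt = build_matrix(values["p_3to4_trt"], values["p_4to5_trt"],
                             mortality, cfg.hd_fraction, cfg.ordering)
        trace_ctl = evaluate_strategy(Strategy("control", m_ctl, payoffs_ctl), cfg)
        trace_trt = evaluate_strategy(Strategy("treatment", m_trt, payoffs_trt), cfg)
        return compare(
            (trace_ctl.total_cost, trace_ctl.total_qalys),
            (trace_trt.total_cost, trace_trt.total_qalys),
            wtp=cfg.wtp,
        )

    return evaluator


def build_param_specs(base_values: Mapping[str, float]) -> list:
    """OWSA/PSA specifications for every model parameter.

    Costs are gamma, probabilities/proportions/utilities beta, the discount
    rate degenerate in the PSA (varied only in the tornado); all ranges are
    +/-30% of base in the absence of reported CIs, with unit-interval
    quantities clipped.
    """
    specs = []
    for name, value in base_values.items():
        if name.startswith("cost_") or name == "drug_daily_tablets":
            family = "gamma"
        elif name == "discount_rate":
            family = "degenerate"
        else:  # utilities, mortalities, transition probabilities, fractions
            family = "beta"
        specs.append(ParamSpec(name=name, base=float(value), psa_family=family))
    return specs


def estimate_arm_transitions(
    config: dict,
    scr_shift_trt: float,
    seed: int,
    n_patients: Optional[int] = None,
) -> dict:
    """Microsimulation step: per-arm annual transition probabilities.

    ``design: separate`` (default) estimates the 3->4 probability on a
    stage-3 cohort and the 4->5 probability on a stage-4 cohort;
    ``design: common`` uses the stage-3 cohort for both.  The two arms share
    cohorts (common random numbers); the control arm has zero shift.
    """
    ms = config.get("microsim", {})
    design = ms.get("design", "separate")
    horizon = int(ms.get("horizon_years", 40))
    conversion = ms.get("conversion", "exponential")
    rule = StagingRule.from_dict(config.get("staging", {}))

    cohort_cfg = dict(config["cohort"])
    cohort_cfg.pop("seed", None)
    if n_patients is not None:
        cohort_cfg["n_patients"] = n_patients
    spec = CohortSpec(**cohort_cfg, seed=seed)
    cohort3 = sample_cohort(spec, stage=3)
    cohort4 = sample_cohort(spec, stage=4)

    applies = frozenset(config.get("effect", {}).get("applies_to", (3, 4)))
    out = {}
    audits = {}
    for arm, shift in (("ctl", 0.0), ("trt", float(scr_shift_trt))):
        effect = ArmEffect(scr_shift=shift, applies_to=applies)
        if design == "common":
            est = estimate_transitions(cohort3, effect, rule, horizon, conversion)
            out[f"p_3to4_{arm}"] = est.p_3to4
            out[f"p_4to5_{arm}"] = est.p_4to5
            audits[arm] = {"common": est.to_dict()}
        else:
            est3 = estimate_transitions(cohort3, effect, rule, horizon,
                                        conversion, which=("3to4",))
            est4 = estimate_transitions(cohort4, effect, rule, horizon,
                                        conversion, which=("4to5",))
            out[f"p_3to4_{arm}"] = est3.p_3to4
            out[f"p_4to5_{arm}"] = est4.p_4to5
            audits[arm] = {"stage3_cohort": est3.to_dict(),
                           "stage4_cohort": est4.to_dict()}
    out["audit"] = audits
    return out


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    timestamp: str
    seed: int
    stage_seeds: dict
    config_hash: str
    outputs: dict
    version: str = __version__
    pooling: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    config: dict
    pooled: "object"
    meta_regressions: dict
    transitions: dict
    base_case: "object"
    tornado: pd.DataFrame
    psa: "object"
    ceac_curve: pd.DataFrame
    prob_ce_wtp: float
    prob_ce_wtp3x: float
    manifest: RunManifest


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("trials", "cohort", "psa")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(
    config: Union[None, str, Path, dict] = None,
    trials: Union[None, str, Path, Sequence[TrialRecord]] = None,
    out_dir: Union[None, str, Path] = None,
    seed: int = 0,
    n_draws: Optional[int] = None,
    n_patients: Optional[int] = None,
) -> PipelineResult:
    """Run the full analysis and (optionally) write the result bundle.

    Parameters default to the packaged synthetic fixtures: a generated
    parameter config and a generated trial table with true WMD -19 umol/L.
    ``n_draws``/``n_patients`` override the config's PSA and cohort sizes.
    """
    from .synth import TrialGenSpec, gen_param_config, gen_trials

    seeds = _stage_seeds(seed)

    if config is None:
        config = gen_param_config(seed=seed)
    elif not isinstance(config, dict):
        config = load_config(config)

    if trials is None:
        trial_records = gen_trials(TrialGenSpec(seed=seeds["trials"]))
    elif isinstance(trials, (str, Path)):
        trial_records = read_trials_csv(trials)
    else:
        trial_records = list(trials)

    # --- meta-analysis ---------------------------------------------------
    pooler = EffectPooler(rule="auto").fit(trial_records)
    pooled = pooler.result_
    logger.info(
        "pooled WMD %.2f umol/L [%s], I2=%.3f, p_Q=%.3g",
        pooled.md, pooled.model, pooled.I2, pooled.p_Q,
    )
    regressions = {}
    for cov in COVARIATE_NAMES:
        try:
            regressions[cov] = meta_regress(trial_records, cov)
        except Exception as exc:
            logger.warning("meta-regression on %s skipped: %s", cov, exc)

    # --- microsimulation -------------------------------------------------
    transitions = estimate_arm_transitions(
        config, scr_shift_trt=pooled.md, seed=seeds["cohort"],
        n_patients=n_patients,
    )

    # --- Markov base case ------------------------------------------------
    evaluator = make_evaluator(config)
    base_values = base_param_values(config, transitions)
    base_case = evaluator(base_values)

    # --- sensitivity -----------------------------------------------------
    specs = build_param_specs(base_values)
    tornado = one_way_sa(specs, evaluator, metric="icer")
    draws = run_psa(
        specs, evaluator,
        n_draws=int(n_draws if n_draws is not None
                    else config.get("psa", {}).get("n_draws", 1000)),
        seed=seeds["psa"],
    )
    wtp = float(config["model"]["wtp"])
    wtp3 = float(config["model"].get("wtp_3x", 3 * wtp))
    grid = np.arange(0.0, wtp3 + 1000.0, 1000.0)
    curve = ceac(draws, grid)
    point = ceac(draws, [wtp, wtp3])
    prob_wtp = float(point["prob_cost_effective"].iloc[0])
    prob_wtp3 = float(point["prob_cost_effective"].iloc[1])

    manifest = RunManifest(
        timestamp=datetime.now(timezone.utc).isoformat(),
        seed=int(seed),
        stage_seeds=seeds,
        config_hash=_config_hash(config),
        outputs={},
        pooling={"model": pooled.model, "I2": pooled.I2, "p_Q": pooled.p_Q},
    )
    result = PipelineResult(
        config=config,
        pooled=pooled,
        meta_regressions=regressions,
        transitions=transitions,
        base_case=base_case,
        tornado=tornado,
        psa=draws,
        ceac_curve=curve,
        prob_ce_wtp=prob_wtp,
        prob_ce_wtp3x=prob_wtp3,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), trial_records)
    return result


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n",
                    encoding="utf-8")


def _write_bundle(result: PipelineResult, out_dir: Path,
                  trial_records: Sequence[TrialRecord]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def _p(name: str) -> Path:
        outputs[name] = str(out_dir / name)
        return out_dir / name

    _json_dump(result.pooled.to_dict(), _p("meta_pooled.json"))
    _json_dump({k: v.to_dict() for k, v in result.meta_regressions.items()},
               _p("meta_regression.json"))
    forest_table(trial_records).to_csv(_p("forest.csv"), index=False)
    _json_dump(result.transitions, _p("transitions.json"))
    _json_dump(result.base_case.to_dict(), _p("base_case.json"))
    result.tornado.to_csv(_p("tornado.csv"), index=False)
    scatter = pd.concat([result.psa.params, result.psa.results], axis=1)
    scatter.to_csv(_p("psa_scatter.csv"), index=False)
    result.ceac_curve.to_csv(_p("ceac.csv"), index=False)
    _json_dump(
        {
            "prob_cost_effective_at_wtp": result.prob_ce_wtp,
            "prob_cost_effective_at_wtp_3x": result.prob_ce_wtp3x,
            "n_draws": result.psa.n_draws,
            "n_resampled": result.psa.n_resampled,
        },
        _p("psa_summary.json"),
    )
    save_config(result.config, _p("config_used.yaml"))
    result.manifest.outputs = outputs
    _json_dump(result.manifest.to_dict(), out_dir / "manifest.json")
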