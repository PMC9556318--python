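"""End-to-end orchestration of the six-stage evidence pipeline for one pair.

Stages: read and validate observations -> fit the trimmed ensemble signal ->
test/select bias covariates -> mixed-effects heterogeneity fit (with Fisher
information on gamma) -> Egger publication-bias test -> curve draws, BPRF,
ROS and star rating; for cardiovascular pairs with age-specific data, the age
attenuation stages run afterwards.  One global seed fans out to per-stage
seeds through numpy SeedSequence spawning (stage order: knots, draws, age),
so each stage is individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bias_model import (
    BiasCovariateEffect,
    bias_report,
    encode_bias_matrix,
    select_bias_covariates,
)
from .cvd_age import (
    AgeAttenuation,
    AgeGroup,
    adjust_curve_eq1,
    attenuation_factors,
    fit_age_pattern,
    reference_age_group,
)
from .data_model import PairConfig, RiskObservation, read_observations
from .evidence import (
    EvidenceScore,
    RiskCurveSet,
    risk_at_doses,
    summarize_pair,
)
from .heterogeneity import (
    HeterogeneityFit,
    fit_mixed_effects,
    fixed_effect_residuals,
)
from .pub_bias import PublicationBiasReport, egger_test, total_sd
from .signal_model import (
    SignalModel,
    evaluate_signal,
    fit_ensemble,
    linear_member,
)


@dataclass
class PipelineResult:
    """All fitted artifacts for one risk-outcome pair."""

    evidence: EvidenceScore
    curves: RiskCurveSet
    het: HeterogeneityFit
    bias_effects: list[BiasCovariateEffect]
    pub_bias: PublicationBiasReport
    signal: SignalModel
    config: PairConfig
    provenance: dict
    age: dict | None = None

    def summary(self) -> dict:
        e = self.evidence
        return {
            "outcome": self.config.outcome_name,
            "ros": e.ros,
            "stars": e.stars,
            "average_bprf": e.average_bprf,
            "average_increased_risk_pct": e.average_increased_risk_pct,
            "exposure_p15": e.exposure_p15,
            "exposure_p85": e.exposure_p85,
            "is_binary": e.is_binary,
            "pub_bias_flag": self.pub_bias.flagged,
            "egger_slope": None
            if not np.isfinite(self.pub_bias.egger_slope)
            else self.pub_bias.egger_slope,
            "egger_p": self.pub_bias.p_value,
            "heterogeneity": self.het.summary(),
            "bias": bias_report(self.bias_effects),
            "trimmed_rows": sorted(self.signal.trimmed_ids),
            "provenance": self.provenance,
        }


def _config_hash(config: PairConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _binary_signal(observations: Sequence[RiskObservation], config: PairConfig) -> SignalModel:
    """Degenerate signal for binary pairs: s(x) = x, so every contrast is 1.

    Trimming still applies, against the inverse-variance weighted mean.
    """
    n = len(observations)
    y = np.array([o.log_effect for o in observations])
    w = 1.0 / np.array([o.se_log for o in observations])
    h = math.ceil(config.trim_fraction * n) if config.trim_fraction > 0 else 0
    trimmed: np.ndarray = np.array([], dtype=int)
    for _ in range(20):
        active = np.setdiff1d(np.arange(n), trimmed)
        mean = np.average(y[active], weights=w[active] ** 2)
        if h == 0:
            break
        resid = np.abs((y - mean) * w)
        new_trimmed = np.sort(np.argsort(resid, kind="stable")[-h:])
        if np.array_equal(new_trimmed, trimmed):
            break
        trimmed = new_trimmed
    member = linear_member(1.0)
    return SignalModel(
        members=[member],
        weights=np.array([1.0]),
        trimmed_ids=frozenset(int(i) for i in trimmed),
    )


def _ensure_scale(signal: SignalModel, config: PairConfig) -> SignalModel:
    """Replace a numerically flat signal with a unit ramp so beta stays defined."""
    probe = evaluate_signal(signal, np.linspace(0, signal.xmax, 64))
    if np.max(np.abs(probe)) > 1e-9:
        return signal
    return SignalModel(
        members=[linear_member(signal.xmax)],
        weights=np.array([1.0]),
        trimmed_ids=signal.trimmed_ids,
    )


def run_pair(
    data: str | Path | Sequence[RiskObservation],
    config: PairConfig | str | Path,
    out_dir: str | Path | None = None,
    age_data: str | Path | pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full pipeline for one risk-outcome pair.

    ``data`` is an observation CSV path or an already validated observation
    list; ``age_data`` (CVD pairs only) is the age-specific binary-RR table.
    Identical config and seed reproduce every numeric output exactly.
    """
    if not isinstance(config, PairConfig):
        config = PairConfig.from_json(config)
    observations = (
        list(data)
        if not isinstance(data, (str, Path))
        else read_observations(data, config)
    )
    ss = np.random.SeedSequence(config.seed)
    rng_knots, rng_draws, rng_age = (np.random.default_rng(c) for c in ss.spawn(3))

    if config.is_binary:
        signal = _binary_signal(observations, config)
        effects: list[BiasCovariateEffect] = []
    else:
        signal = _ensure_scale(fit_ensemble(observations, config, rng=rng_knots), config)
        effects = select_bias_covariates(observations, signal, config)

    keep = np.ones(len(observations), dtype=bool)
    if signal.trimmed_ids:
        keep[list(signal.trimmed_ids)] = False
    obs_u = [o for o, k in zip(observations, keep) if k]
    s_all = signal.design_values(observations)
    s_u = s_all[keep]
    Z = encode_bias_matrix(observations)
    selected = [e for e in effects if e.selected]
    interactions = (
        np.column_stack([Z[e.name].values[keep] * s_u for e in selected])
        if selected
        else None
    )
    het = fit_mixed_effects(obs_u, s_u, interactions)

    residuals = fixed_effect_residuals(het)
    se_u = np.array([o.se_log for o in obs_u])
    tsd = total_sd(se_u, s_u, het.gamma_star)
    pub = egger_test(residuals, tsd, config.direction)

    score, curves = summarize_pair(observations, signal, het, config, rng=rng_draws)

    age_result = None
    if config.is_cvd and age_data is not None:
        age_df = (
            age_data
            if isinstance(age_data, pd.DataFrame)
            else pd.read_csv(age_data)
        )
        ref_group = reference_age_group(observations)
        age_curve = fit_age_pattern(age_df)
        atten = attenuation_factors(age_curve, ref_group, config.n_draws, rng=rng_age)
        rr_draws = np.exp(curves.draws)
        group_frames = []
        for g_idx, group in enumerate(atten.age_groups):
            adjusted = adjust_curve_eq1(rr_draws, atten.af_draws[:, g_idx])
            group_frames.append(
                pd.DataFrame(
                    {
                        "age_group": group.label,
                        "dose": curves.grid,
                        "mean_rr": adjusted.mean(axis=0),
                        "ui_lower": np.quantile(adjusted, 0.025, axis=0),
                        "ui_upper": np.quantile(adjusted, 0.975, axis=0),
                    }
                )
            )
        age_result = {
            "reference_group": ref_group.label,
            "attenuation": atten,
            "age_curves": pd.concat(group_frames, ignore_index=True),
        }

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }
    result = PipelineResult(
        evidence=score,
        curves=curves,
        het=het,
        bias_effects=effects,
        pub_bias=pub,
        signal=signal,
        config=config,
        provenance=provenance,
        age=age_result,
    )
    if out_dir is not None:
        write_outputs(result, out_dir, obs_u, s_u, residuals, tsd)
    return result


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    obs_u: Sequence[RiskObservation],
    s_u: np.ndarray,
    residuals: np.ndarray,
    tsd: np.ndarray,
) -> None:
    """Emit summary.json, curve CSVs, the summary-table row and funnel data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)

    curves = result.curves
    pd.DataFrame(
        {
            "dose": curves.grid,
            "mean_log_rr": curves.mean_log_rr,
            "bprf_log": result.evidence.bprf_log,
            "ui_lower": curves.ui_lower,
            "ui_upper": curves.ui_upper,
        }
    ).to_csv(out / "risk_curve.csv", index=False)
    pd.DataFrame(
        curves.draws, columns=[f"{d:.1f}" for d in curves.grid]
    ).to_csv(out / "curve_draws.csv", index=False)

    doses = [5, 10, 20, 40, result.evidence.exposure_p85]
    row = risk_at_doses(curves, doses)
    row["ros"] = round(result.evidence.ros, 2)
    row["stars"] = result.evidence.stars
    row.to_csv(out / "table_row.csv", index=False)

    pd.DataFrame(
        {
            "study_id": [o.study_id for o in obs_u],
            "residual": residuals,
            "total_sd": tsd,
            "trimmed": False,
        }
    ).to_csv(out / "funnel.csv", index=False)
    if result.age is not None:
        result.age["age_curves"].to_csv(out / "age_specific_curves.csv", index=False)
        result.age["attenuation"].to_frame().to_csv(
            out / "age_attenuation.csv", index=False
        )
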