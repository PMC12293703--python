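"""Three-step network MR orchestration and mediation-proportion arithmetic.

A network analysis runs three two-sample MR legs — exposure→outcome (total
effect), exposure→mediator (screened in a discovery panel and confirmed in a
replication panel), and mediator→outcome — and decomposes the total effect
by the product-of-coefficients ratio

    proportion mediated = (β_xm · β_my) / β_total

with all binary-trait effects entered on the log-odds scale.  The reverse
direction (mediator→exposure→outcome) is assessed symmetrically with the
mediator's own instruments.  Each leg carries the full sensitivity battery
and the fixed-vs-random-effects reporting rule.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import EggerResult, MrEstimate, Z95, egger, ivw_fixed, ivw_mre
from .exceptions import ConfigurationError, EstimationError, NetmrError
from .harmonize import HarmonizedSet, harmonize, write_audit
from .instruments import clump, select_significant
from .io import LdTable, SummaryDataset
from .sensitivity import (
    HeterogeneityStats,
    LooResult,
    PressoResult,
    cochran_q,
    iterative_outlier_removal,
    leave_one_out,
    robustness_policy,
)


@dataclass
class StepConfig:
    """Thresholds and knobs shared by every MR leg."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2_min: float = 0.8
    palindrome_window: float = 0.08
    alpha: float = 0.05
    presso_nsim: int = 1000
    presso_max_iter: int = 5
    seed: int = 0
    exclude_ids: tuple[str, ...] = ()


@dataclass
class StepResult:
    """One MR leg: the reported estimate plus its full diagnostic record."""

    step: str
    exposure_name: str
    outcome_name: str
    estimate: MrEstimate
    rationale: str
    fe: MrEstimate
    mre: MrEstimate | None
    egger: EggerResult | None
    heterogeneity: HeterogeneityStats
    harmonized: HarmonizedSet
    instrument_ids: list[str]
    presso: list[PressoResult] = field(default_factory=list)
    loo: LooResult | None = None
    removed_outliers: list[str] = field(default_factory=list)


def _step_seed(base: int, step: str) -> int:
    return (base + zlib.crc32(step.encode())) % (2**31 - 1)


def run_step(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: StepConfig,
    ld: LdTable | None = None,
    step: str = "exposure_outcome",
    instrument_ids: list[str] | None = None,
) -> StepResult:
    """Select → clump → harmonize → estimate → sensitivity → reporting rule.

    ``instrument_ids`` overrides selection (e.g. a pre-validated list).
    Errors from any stage are re-raised with the step label prepended.
    """
    try:
        if instrument_ids is None:
            ids = select_significant(exposure, config.p_threshold)
            ids = clump(ids, ld or LdTable(), config.clump_r2)
        else:
            ids = list(instrument_ids)
        if config.exclude_ids:
            excl = set(config.exclude_ids)
            ids = [i for i in ids if i not in excl]
        if not ids:
            raise EstimationError("no instruments after selection/clumping")
        hset = harmonize(exposure, outcome, ids, config.palindrome_window,
                         ld, config.proxy_r2_min)
        if hset.k < 2:
            raise EstimationError(f"only {hset.k} harmonized SNP(s); need >= 2")

        presso_results: list[PressoResult] = []
        removed: list[str] = []
        if hset.k >= 4 and config.presso_nsim > 0:
            # keep the Bonferroni floor k/(n_sim+1) below alpha so the
            # outlier test retains power at large instrument counts
            n_sim = max(config.presso_nsim, int(math.ceil(hset.k / config.alpha)) + 1)
            hset, presso_results, removed = iterative_outlier_removal(
                hset, n_sim=n_sim, seed=_step_seed(config.seed, step),
                global_alpha=config.alpha, max_iter=config.presso_max_iter,
            )

        fe = ivw_fixed(hset)
        het = cochran_q(hset)
        mre = ivw_mre(hset) if hset.k >= 3 else None
        eg = egger(hset) if hset.k >= 3 else None
        loo = leave_one_out(hset) if hset.k >= 3 else None
        chosen, rationale = robustness_policy(
            het, eg.intercept_p if eg is not None else 1.0, fe, mre if mre is not None else fe
        )
        return StepResult(step, exposure.trait_name, outcome.trait_name, chosen,
                          rationale, fe, mre, eg, het, hset, ids,
                          presso=presso_results, loo=loo, removed_outliers=removed)
    except NetmrError as e:
        raise type(e)(f"[{step}: {exposure.trait_name} -> {outcome.trait_name}] {e}") from e


@dataclass(frozen=True)
class ReplicationVerdict:
    passed: bool
    reason: str


def replication_filter(discovery: StepResult, replication: StepResult,
                       alpha: float = 0.05) -> ReplicationVerdict:
    """Pass iff both legs reach p < alpha *and* the effect directions agree."""
    if (discovery.exposure_name != replication.exposure_name
            or discovery.outcome_name != replication.outcome_name):
        raise ConfigurationError(
            f"replication_filter: trait mismatch "
            f"({discovery.exposure_name}->{discovery.outcome_name} vs "
            f"{replication.exposure_name}->{replication.outcome_name})"
        )
    p_d, p_r = discovery.estimate.pvalue, replication.estimate.pvalue
    if p_d >= alpha or p_r >= alpha:
        return ReplicationVerdict(False, f"not significant in both (p={p_d:.3g}, {p_r:.3g})")
    if np.sign(discovery.estimate.beta) != np.sign(replication.estimate.beta):
        return ReplicationVerdict(False, "sign_discordant")
    return ReplicationVerdict(True, "replicated")


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of one exposure→mediator→outcome path."""

    exposure: str
    mediator: str
    outcome: str
    beta_total: float
    beta_xm: float
    beta_my: float
    indirect: float
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float
    out_of_range: bool = False


def mediation_proportion(
    beta_total: float,
    beta_xm: float,
    beta_my: float,
    se_total: float = 0.0,
    se_xm: float = 0.0,
    se_my: float = 0.0,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Mediated proportion (β_xm·β_my)/β_total with a delta-method SE.

    Binary-trait effects must already be on the log-OR scale (``ln OR``).
    The three estimates come from distinct samples and are treated as
    independent.  |proportion| > 1 ("inconsistent mediation") is reported
    with a warning, not an error.
    """
    if beta_total == 0:
        raise EstimationError("beta_total is 0: mediated proportion undefined")
    indirect = beta_xm * beta_my
    proportion = indirect / beta_total
    var = ((beta_my / beta_total) ** 2 * se_xm ** 2
           + (beta_xm / beta_total) ** 2 * se_my ** 2
           + (indirect / beta_total ** 2) ** 2 * se_total ** 2)
    se = float(np.sqrt(var))
    out_of_range = abs(proportion) > 1
    if out_of_range:
        warnings.warn(
            f"mediated proportion {proportion:.3f} outside [-1, 1] "
            f"({exposure}->{mediator}->{outcome}): inconsistent mediation",
            stacklevel=2,
        )
    return MediationResult(exposure, mediator, outcome, beta_total, beta_xm, beta_my,
                           indirect, proportion, se,
                           proportion - Z95 * se, proportion + Z95 * se, out_of_range)


def bootstrap_proportion(
    beta_total: float, beta_xm: float, beta_my: float,
    se_total: float, se_xm: float, se_my: float,
    n_draws: int = 10_000, *, seed: int,
) -> tuple[float, tuple[float, float]]:
    """Parametric-bootstrap (SE, 95% percentile CI) cross-check of the
    delta-method uncertainty; draws the three effects independently normal."""
    rng = np.random.default_rng(seed)
    tot = rng.normal(beta_total, se_total, n_draws)
    xm = rng.normal(beta_xm, se_xm, n_draws)
    my = rng.normal(beta_my, se_my, n_draws)
    props = xm * my / tot
    lo, hi = np.percentile(props, [2.5, 97.5])
    return float(np.std(props, ddof=1)), (float(lo), float(hi))


@dataclass
class MediatorPair:
    name: str
    discovery: SummaryDataset
    replication: SummaryDataset


@dataclass
class NetworkConfig:
    exposure: SummaryDataset
    outcomes: list[SummaryDataset]
    mediators: list[MediatorPair] = field(default_factory=list)
    ld: LdTable | None = None
    step: StepConfig = field(default_factory=StepConfig)
    bonferroni: bool = False


@dataclass
class NetworkReport:
    exposure_name: str
    step1: dict[str, StepResult]
    mediator_discovery: dict[str, StepResult] = field(default_factory=dict)
    mediator_replication: dict[str, StepResult] = field(default_factory=dict)
    verdicts: dict[str, ReplicationVerdict] = field(default_factory=dict)
    qualified_mediators: list[str] = field(default_factory=list)
    mediator_outcome: dict[tuple[str, str], StepResult] = field(default_factory=dict)
    mediator_exposure: dict[str, StepResult] = field(default_factory=dict)
    mediation_forward: list[MediationResult] = field(default_factory=list)
    mediation_reverse: list[MediationResult] = field(default_factory=list)
    instrument_overlap: dict[str, list[str]] = field(default_factory=dict)

    def all_steps(self) -> list[StepResult]:
        return (list(self.step1.values())
                + list(self.mediator_discovery.values())
                + list(self.mediator_replication.values())
                + list(self.mediator_outcome.values())
                + list(self.mediator_exposure.values()))


def run_network(config: NetworkConfig) -> NetworkReport:
    """Execute the full three-step network design, forward and reverse.

    Step 1 estimates the exposure's total effect on every outcome; step 2
    screens candidate mediators (discovery then replication, both at
    p < alpha with concordant direction); step 3 estimates each qualified
    mediator's effect on every outcome using the mediator's own instruments.
    Forward mediated proportions are computed wherever all three legs pass
    the screen; the reverse direction swaps the roles of exposure and
    mediator.  An empty mediation table is a valid result, not an error.
    """
    alpha = config.step.alpha
    if config.bonferroni and config.mediators:
        alpha = alpha / len(config.mediators)

    exposure = config.exposure
    report = NetworkReport(exposure.trait_name, step1={})

    for outcome in config.outcomes:
        report.step1[outcome.trait_name] = run_step(
            exposure, outcome, config.step, config.ld, step="exposure_outcome")

    for m in config.mediators:
        disc = run_step(exposure, m.discovery, config.step, config.ld,
                        step="exposure_mediator_discovery")
        rep = run_step(exposure, m.replication, config.step, config.ld,
                       step="exposure_mediator_replication")
        report.mediator_discovery[m.name] = disc
        report.mediator_replication[m.name] = rep
        verdict = replication_filter(disc, rep, alpha)
        report.verdicts[m.name] = verdict
        if verdict.passed:
            report.qualified_mediators.append(m.name)

    exposure_instruments: set[str] = set()
    for res in report.step1.values():
        exposure_instruments.update(res.instrument_ids)

    for m in config.mediators:
        if m.name not in report.qualified_mediators:
            continue
        mx = run_step(m.discovery, exposure, config.step, config.ld, step="mediator_exposure")
        report.mediator_exposure[m.name] = mx
        report.instrument_overlap[m.name] = sorted(
            exposure_instruments.intersection(mx.instrument_ids))
        for outcome in config.outcomes:
            my = run_step(m.discovery, outcome, config.step, config.ld, step="mediator_outcome")
            report.mediator_outcome[(m.name, outcome.trait_name)] = my

            total = report.step1[outcome.trait_name]
            disc = report.mediator_discovery[m.name]
            if (total.estimate.pvalue < alpha and disc.estimate.pvalue < alpha
                    and my.estimate.pvalue < alpha):
                report.mediation_forward.append(mediation_proportion(
                    total.estimate.beta, disc.estimate.beta, my.estimate.beta,
                    total.estimate.se, disc.estimate.se, my.estimate.se,
                    exposure=exposure.trait_name, mediator=m.name,
                    outcome=outcome.trait_name,
                ))
            # reverse: mediator -> exposure -> outcome
            if (my.estimate.pvalue < alpha and mx.estimate.pvalue < alpha
                    and total.estimate.pvalue < alpha):
                report.mediation_reverse.append(mediation_proportion(
                    my.estimate.beta, mx.estimate.beta, total.estimate.beta,
                    my.estimate.se, mx.estimate.se, total.estimate.se,
                    exposure=m.name, mediator=exposure.trait_name,
                    outcome=outcome.trait_name,
                ))
    return report


def _estimate_row(step: StepResult, est: MrEstimate) -> dict:
    row = {
        "step": step.step, "exposure": step.exposure_name, "outcome": step.outcome_name,
        "method": est.method, "k": est.k, "beta": est.beta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.pvalue,
        "or": None, "or_ci_low": None, "or_ci_high": None,
    }
    if est.or_scale is not None:
        row["or"], row["or_ci_low"], row["or_ci_high"] = est.or_scale
    return row


def write_report(report: NetworkReport, outdir) -> None:
    """Emit estimates.tsv, sensitivity.tsv, mediation.tsv, per-step audit TSVs
    and a machine-readable summary.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    est_rows, sens_rows = [], []
    for step in report.all_steps():
        for est in filter(None, (step.estimate, step.fe, step.mre,
                                 step.egger.slope if step.egger else None)):
            est_rows.append(_estimate_row(step, est))
        last_presso = step.presso[-1] if step.presso else None
        sens_rows.append({
            "step": step.step, "exposure": step.exposure_name, "outcome": step.outcome_name,
            "q": step.heterogeneity.q, "df": step.heterogeneity.df,
            "q_p": step.heterogeneity.pvalue, "i2": step.heterogeneity.i2,
            "egger_intercept": step.egger.intercept if step.egger else None,
            "intercept_p": step.egger.intercept_p if step.egger else None,
            "presso_global_p": last_presso.global_p if last_presso else None,
            "n_outliers": len(step.removed_outliers),
            "distortion_p": last_presso.distortion_p if last_presso else None,
            "chosen_method": step.estimate.method,
            "loo_flags": ",".join(step.loo.flags) if step.loo else "",
        })
    pd.DataFrame(est_rows).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    pd.DataFrame(sens_rows).to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)

    med_rows = []
    for direction, results in (("forward", report.mediation_forward),
                               ("reverse", report.mediation_reverse)):
        for r in results:
            med_rows.append({
                "direction": direction, "exposure": r.exposure, "mediator": r.mediator,
                "outcome": r.outcome, "beta_total": r.beta_total, "beta_xm": r.beta_xm,
                "beta_my": r.beta_my, "indirect": r.indirect,
                "proportion": r.proportion, "proportion_pct": 100.0 * r.proportion,
                "proportion_se": r.proportion_se,
                "ci_low": r.ci_low, "ci_high": r.ci_high, "out_of_range": r.out_of_range,
            })
    pd.DataFrame(med_rows, columns=[
        "direction", "exposure", "mediator", "outcome", "beta_total", "beta_xm", "beta_my",
        "indirect", "proportion", "proportion_pct", "proportion_se", "ci_low", "ci_high",
        "out_of_range",
    ]).to_csv(outdir / "mediation.tsv", sep="\t", index=False)

    audit_dir = outdir / "audit"
    audit_dir.mkdir(exist_ok=True)
    for step in report.all_steps():
        name = f"{step.step}__{step.exposure_name}__{step.outcome_name}.tsv"
        write_audit(step.harmonized, audit_dir / name)

    summary = {
        "exposure": report.exposure_name,
        "qualified_mediators": report.qualified_mediators,
        "verdicts": {k: {"passed": v.passed, "reason": v.reason}
                     for k, v in report.verdicts.items()},
        "instrument_overlap": report.instrument_overlap,
        "step1": {k: _estimate_row(v, v.estimate) for k, v in report.step1.items()},
        "mediation_forward": [vars(r) for r in report.mediation_forward],
        "mediation_reverse": [vars(r) for r in report.mediation_reverse],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
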