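"""Two-sample GWAS summary statistics under a known causal chain.

The generator emulates the structure of consortium summary-statistics panels:
independent genome-wide-significant instruments for an exposure, separate
(non-overlapping) samples for exposure, mediator (discovery and replication)
and outcome, and a configurable exposure → mediator → outcome causal model

    mediator = γ_xm · exposure-genetics + mediator-specific genetics
    outcome  = θ_direct · exposure + θ_my · mediator (+ pleiotropy)

Exposure instruments are drawn by rejection sampling of true effects until
they pass genome-wide significance at the exposure sample size, so selection
acts on the *truth* and the observed effects — re-drawn around the truth in
each virtual panel — are free of winner's curse, as in a clean two-sample
design.  The mediator gets its own instrument SNPs (zero exposure effect)
so that the mediator→outcome leg of a network analysis is identified and
its instruments are disjoint from the exposure's.

Every dataset records the ground truth in the returned study, so pipeline
tests can score estimates against known parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import GENOME_WIDE_P
from .io import LdTable, SummaryDataset, VariantAssociation, write_ld_table, write_summary_table

# ordered non-palindromic allele pairs (strand logic stays unambiguous)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Pleiotropy:
    """Direct SNP→outcome effects violating the exclusion restriction."""

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none", 0.0, 0.0)

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", 0.0, sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean, sd)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic study.

    Defaults describe a well-powered biobank-scale design: 100 independent
    instruments per trait at n = 100,000 per panel, per-SNP effect scales
    that put instrument F-statistics in the tens-to-thousands range typical
    of strong published instruments.
    """

    k_snps: int = 100
    k_snps_mediator: int = 100
    n_exp: int = 100_000
    n_med: int = 100_000
    n_med_rep: int = 100_000
    n_out: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_exp_scale: float = 0.03
    beta_med_scale: float = 0.05
    gamma_xm: float = -0.3
    theta_my: float = 0.4
    theta_direct: float = -0.05
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    outlier_frac: float = 0.0
    outcome_binary: bool = False
    prevalence: float = 0.1
    ld_block_size: int = 1
    ld_block_r2: float = 0.8
    scramble_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        for name in ("n_exp", "n_med", "n_med_rep", "n_out"):
            if getattr(self, name) <= 100:
                raise ConfigurationError(f"{name} must exceed 100")
        if not 0 <= self.outlier_frac <= 0.3:
            raise ConfigurationError("outlier_frac outside [0, 0.3]")
        if self.k_snps < 1:
            raise ConfigurationError("k_snps must be >= 1")


@dataclass
class SyntheticStudy:
    """Generated summary panels plus the truth that produced them."""

    exposure: SummaryDataset
    mediator: SummaryDataset
    mediator_replication: SummaryDataset
    outcome: SummaryDataset
    truth: SimulationConfig
    exposure_instrument_ids: list[str]
    mediator_instrument_ids: list[str]
    outlier_ids: list[str]
    ld: LdTable | None = None
    #: per-SNP generating effects: variant_id, beta_x, beta_m, beta_y
    true_effects: pd.DataFrame | None = None


def theoretical_effects(config: SimulationConfig) -> tuple[float, float, float]:
    """(total, indirect, proportion) implied by the generating parameters."""
    indirect = config.gamma_xm * config.theta_my
    total = config.theta_direct + indirect
    if total == 0:
        raise ConfigurationError("total effect is 0: mediated proportion undefined")
    return total, indirect, indirect / total


def _quant_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _binary_se(maf: np.ndarray, n: float, prev: float) -> np.ndarray:
    return np.sqrt(1.0 / (n * prev * (1.0 - prev)) / (2.0 * maf * (1.0 - maf)))


def _truncated_effects(rng, scale: float, se: np.ndarray, z_thr: float) -> np.ndarray:
    """True effects ~ N(0, scale²) conditioned on genome-wide significance."""
    frac = 2.0 * stats.norm.sf(z_thr * se / scale)
    if np.any(frac < 1e-4):
        raise ConfigurationError(
            "truncation unsatisfiable: expected significant fraction below 1e-4 "
            f"(min {frac.min():.2e}); raise the effect scale or sample size"
        )
    out = np.zeros(se.shape)
    todo = np.ones(se.shape, dtype=bool)
    while todo.any():
        draw = rng.normal(0.0, scale, size=int(todo.sum()))
        ok = np.abs(draw) >= z_thr * se[todo]
        idx = np.flatnonzero(todo)[ok]
        out[idx] = draw[ok]
        todo[idx] = False
    return out


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _dataset(name, trait_type, n, ids, alleles, eaf, beta, se, rng, scramble) -> SummaryDataset:
    p = _pvalues(beta, se)
    records = {}
    modes = rng.integers(0, 4, size=len(ids)) if scramble else np.zeros(len(ids), dtype=int)
    for i, vid in enumerate(ids):
        ea, oa = alleles[i]
        b, f = float(beta[i]), float(eaf[i])
        mode = modes[i]
        if mode in (1, 3):  # report the opposite effect allele
            ea, oa, b, f = oa, ea, -b, 1.0 - f
        if mode in (2, 3):  # report the opposite strand
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        records[vid] = VariantAssociation(vid, ea, oa, b, float(se[i]), float(p[i]), f, float(n))
    return SummaryDataset(name, trait_type, int(n), records)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw one study (all four panels) under ``config``; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    ke, km = config.k_snps, config.k_snps_mediator
    k = ke + km
    ids = [f"rs{i + 1:07d}" for i in range(k)]
    exp_ids, med_ids = ids[:ke], ids[ke:]
    maf = rng.uniform(*config.maf_range, size=k)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]

    se_exp = _quant_se(maf, config.n_exp)
    se_med = _quant_se(maf, config.n_med)
    se_rep = _quant_se(maf, config.n_med_rep)
    se_out = (_binary_se(maf, config.n_out, config.prevalence) if config.outcome_binary
              else _quant_se(maf, config.n_out))

    z_thr = stats.norm.isf(GENOME_WIDE_P / 2.0)
    b_x = np.zeros(k)
    b_x[:ke] = _truncated_effects(rng, config.beta_exp_scale, se_exp[:ke], z_thr)
    b_m_direct = np.zeros(k)
    if km:
        b_m_direct[ke:] = _truncated_effects(rng, config.beta_med_scale, se_med[ke:], z_thr)

    b_m = config.gamma_xm * b_x + b_m_direct
    alpha = np.zeros(k)
    pl = config.pleiotropy
    if pl.kind != "none":
        # pleiotropic effects are expressed per exposure-increasing allele
        # (the orientation Egger regression uses), so a directional mean
        # shifts the intercept rather than cancelling across orientations
        alpha[:ke] = rng.normal(pl.mean, pl.sd, size=ke) * np.sign(b_x[:ke])
    b_y = config.theta_direct * b_x + config.theta_my * b_m + alpha

    n_outlier = int(round(config.outlier_frac * ke))
    outlier_idx = rng.choice(ke, size=n_outlier, replace=False) if n_outlier else np.array([], dtype=int)
    b_y = b_y.copy()
    b_y[outlier_idx] *= 10.0
    outlier_ids = [ids[i] for i in outlier_idx]

    obs_x = b_x + rng.normal(0.0, se_exp)
    obs_m = b_m + rng.normal(0.0, se_med)
    obs_r = b_m + rng.normal(0.0, se_rep)
    obs_y = b_y + rng.normal(0.0, se_out)

    sc = config.scramble_orientation
    exposure = _dataset("exposure", "quantitative", config.n_exp, ids, alleles, maf,
                        obs_x, se_exp, rng, scramble=False)
    mediator = _dataset("mediator", "quantitative", config.n_med, ids, alleles, maf,
                        obs_m, se_med, rng, scramble=sc)
    replication = _dataset("mediator", "quantitative", config.n_med_rep, ids, alleles, maf,
                           obs_r, se_rep, rng, scramble=sc)
    outcome_type = "binary" if config.outcome_binary else "quantitative"
    outcome = _dataset("outcome", outcome_type, config.n_out, ids, alleles, maf,
                       obs_y, se_out, rng, scramble=sc)

    ld = None
    if config.ld_block_size > 1:
        ld = LdTable()
        for start in range(0, ke, config.ld_block_size):
            block = exp_ids[start:start + config.ld_block_size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    ld.set(block[i], block[j], config.ld_block_r2)

    truth_table = pd.DataFrame(
        {"variant_id": ids, "beta_x": b_x, "beta_m": b_m, "beta_y": b_y})
    return SyntheticStudy(exposure, mediator, replication, outcome, config,
                          exp_ids, med_ids, outlier_ids, ld, truth_table)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the four summary panels, the LD table, and a truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary_table(study.exposure, outdir / "exposure.tsv")
    write_summary_table(study.mediator, outdir / "mediator_discovery.tsv")
    write_summary_table(study.mediator_replication, outdir / "mediator_replication.tsv")
    write_summary_table(study.outcome, outdir / "outcome.tsv")
    if study.ld is not None:
        write_ld_table(study.ld, outdir / "ld.tsv")
    truth = asdict(study.truth)
    truth["exposure_instrument_ids"] = study.exposure_instrument_ids
    truth["mediator_instrument_ids"] = study.mediator_instrument_ids
    truth["outlier_ids"] = study.outlier_ids
    total, indirect, proportion = theoretical_effects(study.truth)
    truth["theoretical"] = {"total": total, "indirect": indirect, "proportion": proportion}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=list))
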