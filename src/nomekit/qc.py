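"""Spike-in quality control.

An unmethylated λ-phage spike-in travels through the M.CviPI treatment and
bisulfite conversion with the sample.  Because λ carries no endogenous
methylation, pooled GCH methylation on λ estimates the in vitro enzyme
efficiency, and residual methylation at non-GCH λ cytosines (WCG + OTHER)
estimates the bisulfite conversion failure.  Samples are retained only with
efficiency >= 90% and conversion rate strictly above 98%.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calls import SampleCalls, genome_mean_level

__all__ = ["QCReport", "mcvipi_efficiency", "conversion_rate", "sample_qc", "qc_table"]

EFFICIENCY_MIN = 0.90   # "no less than 90%": boundary passes
CONVERSION_MIN = 0.98   # "higher than 98%": boundary fails


@dataclass
class QCReport:
    sample_id: str
    mcvipi_efficiency: float | None
    conversion_rate: float | None
    n_gch_obs: int
    n_non_gch_obs: int
    passed: bool
    reason: str = ""


def mcvipi_efficiency(lambda_calls: SampleCalls, min_depth: int = 1) -> tuple[float | None, int]:
    """Pooled GCH methylation level over λ: the enzyme's in vitro efficiency.

    Returns (rate, n_observations); rate is None without GCH coverage.
    """
    pooled = genome_mean_level(lambda_calls, "GCH", min_depth=min_depth)
    return pooled.level, pooled.depth


def conversion_rate(lambda_calls: SampleCalls, min_depth: int = 1) -> tuple[float | None, int]:
    """1 - pooled methylation at non-GCH λ cytosines (WCG and OTHER).

    λ has no endogenous methylation and the enzyme targets only GpC, so any
    methylation signal here is conversion failure.
    """
    wcg = genome_mean_level(lambda_calls, "WCG", min_depth=min_depth)
    other = genome_mean_level(lambda_calls, "OTHER", min_depth=min_depth)
    meth = wcg.pooled_meth + other.pooled_meth
    depth = wcg.depth + other.depth
    if depth == 0:
        return None, 0
    return 1.0 - meth / depth, depth


def sample_qc(efficiency: float | None, conversion: float | None) -> tuple[bool, str]:
    """Retention rule: efficiency >= 0.90 AND conversion > 0.98 (boundary-literal)."""
    if efficiency is None:
        return False, "efficiency undefined (no lambda GCH observations)"
    if conversion is None:
        return False, "conversion rate undefined (no lambda non-GCH observations)"
    if efficiency < EFFICIENCY_MIN:
        return False, f"M.CviPI efficiency {efficiency:.4f} < {EFFICIENCY_MIN}"
    if conversion <= CONVERSION_MIN:
        return False, f"bisulfite conversion {conversion:.4f} <= {CONVERSION_MIN}"
    return True, ""


def qc_report(lambda_calls: SampleCalls, min_depth: int = 1) -> QCReport:
    eff, n_gch = mcvipi_efficiency(lambda_calls, min_depth)
    conv, n_non = conversion_rate(lambda_calls, min_depth)
    passed, reason = sample_qc(eff, conv)
    return QCReport(lambda_calls.sample_id, eff, conv, n_gch, n_non, passed, reason)


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    """QC results as a writable table (one row per sample)."""
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in reports],
            "mcvipi_efficiency": [r.mcvipi_efficiency for r in reports],
            "conversion_rate": [r.conversion_rate for r in reports],
            "n_gch_obs": [r.n_gch_obs for r in reports],
            "n_non_gch_obs": [r.n_non_gch_obs for r in reports],
            "pass": [r.passed for r in reports],
            "reason": [r.reason for r in reports],
        }
    )
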