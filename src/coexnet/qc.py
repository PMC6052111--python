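"""Sample-level quality control for combined expression cohorts.

Two complementary outlier tests are run per sample (array):

* dispersion test — the sample's upper-quartile (75th percentile) value is
  compared with the cohort median of upper quartiles; samples deviating by
  more than ``mad_k`` median absolute deviations are flagged;
* distribution test — a two-sample Kolmogorov-Smirnov test of the sample's
  values against the pooled values of all other samples (empirical CDFs);
  samples rejecting at ``ks_alpha`` are flagged.

A sample is discarded only when *both* tests flag it: either test alone is
sensitive to benign biological or technical variation, their conjunction
targets arrays that are globally aberrant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.errors import InsufficientSamplesError
from coexnet.expression import ExpressionMatrix


@dataclass
class QCReport:
    """Per-sample QC statistics and the resulting discard decision."""

    sample_ids: list[str]
    upper_quartile: np.ndarray
    ks_stat: np.ndarray
    ks_pvalue: np.ndarray
    dispersion_flag: np.ndarray
    ks_flag: np.ndarray
    params: dict

    @property
    def discarded(self) -> list[str]:
        """Samples flagged by both the dispersion and the KS test."""
        both = self.dispersion_flag & self.ks_flag
        return [s for s, d in zip(self.sample_ids, both) if d]

    def to_frame(self) -> pd.DataFrame:
        both = self.dispersion_flag & self.ks_flag
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "upper_quartile": self.upper_quartile,
            "ks_stat": self.ks_stat,
            "disp_flag": self.dispersion_flag,
            "ks_flag": self.ks_flag,
            "discarded": both,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_outliers(mat: ExpressionMatrix, *, dispersion_quantile: float = 0.75,
                ks_alpha: float = 1e-3, mad_k: float = 5.0) -> QCReport:
    """Flag outlier samples by upper-quartile dispersion and KS testing.

    Parameters
    ----------
    dispersion_quantile : float
        Quantile summarizing each sample (default 0.75, the upper quartile).
    ks_alpha : float
        Significance level of the two-sample KS test of a sample against
        the pooled remaining samples.
    mad_k : float
        A sample's upper quartile must deviate from the cohort median of
        upper quartiles by more than ``mad_k`` median absolute deviations
        to be a dispersion outlier.

    Returns
    -------
    QCReport
        Per-sample statistics and flags; ``report.discarded`` lists samples
        flagged by both tests.
    """
    n = mat.n_samples
    if n < 3:
        raise InsufficientSamplesError(f"need >= 3 samples, got {n}")
    uq = np.quantile(mat.values, dispersion_quantile, axis=0)
    med = np.median(uq)
    mad = np.median(np.abs(uq - med))
    if mad == 0:
        # identical upper quartiles: only exact deviations can flag
        disp_flag = np.abs(uq - med) > 0
    else:
        disp_flag = np.abs(uq - med) > mad_k * mad

    ks_stat = np.empty(n)
    ks_p = np.empty(n)
    for j in range(n):
        others = np.delete(mat.values, j, axis=1).ravel()
        res = stats.ks_2samp(mat.values[:, j], others, method="asymp")
        ks_stat[j], ks_p[j] = res.statistic, res.pvalue
    ks_flag = ks_p < ks_alpha

    return QCReport(
        sample_ids=list(mat.sample_ids),
        upper_quartile=uq,
        ks_stat=ks_stat,
        ks_pvalue=ks_p,
        dispersion_flag=disp_flag,
        ks_flag=ks_flag,
        params={
            "dispersion_quantile": dispersion_quantile,
            "ks_alpha": ks_alpha,
            "mad_k": mad_k,
        },
    )
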