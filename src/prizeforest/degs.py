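"""No-replicate negative-binomial differential expression.

The experimental design addressed here has exactly two RNA-seq libraries —
one control and one treated sample — with no biological replicates, so the
negative-binomial dispersion cannot be estimated from residual variation.
Instead a fixed biological coefficient of variation (BCV) is supplied, either
estimated from a panel of housekeeping genes or set directly (the study
convention is BCV = 0.045, i.e. dispersion = 0.002025).

Differential calls use an exact conditional test: after equalizing the two
library sizes, the distribution of one count conditional on the pair total is
computed by direct summation of negative-binomial probabilities, and the
two-sided p-value is the total conditional probability of all splits no more
likely than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError, InputError, UnsupportedDesignError

__all__ = [
    "CountMatrix",
    "DispersionModel",
    "DEGFilter",
    "cpm",
    "estimate_bcv",
    "exact_test",
    "log_fold_change",
    "call_degs",
]

#: relative tie tolerance (log scale) when collecting splits no more likely
#: than the observed one; exact symmetric ties are always captured
_TIE_LOG_TOL = 1e-9


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    ``counts`` is a DataFrame indexed by unique gene identifiers with one
    column per sample.  ``lib_sizes`` defaults to the column sums but may be
    overridden (e.g. with externally determined library sizes).
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise InputError("gene_ids must be unique")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise InputError("counts must be nonnegative")
        if not np.allclose(arr, np.rint(arr)):
            raise InputError("counts must be integral")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, dtype=float).reindex(
                self.counts.columns
            )
        if (self.lib_sizes <= 0).any():
            raise InputError("lib_sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, lib_sizes=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(df, lib_sizes=lib_sizes)


@dataclass(frozen=True)
class DispersionModel:
    """Fixed NB dispersion in BCV form: variance = mu + dispersion * mu^2."""

    bcv: float

    def __post_init__(self) -> None:
        if self.bcv <= 0:
            raise InputError("bcv must be positive")

    @property
    def dispersion(self) -> float:
        return self.bcv**2


@dataclass(frozen=True)
class DEGFilter:
    """Thresholds for calling differential genes.

    Defaults follow the study settings: |logFC| >= 2.0 (the PTEN-adequate
    cell line; 1.5 for the PTEN-deficient one), p <= 0.01, FDR <= 0.01, and
    an abundance filter of cpm > 5 in at least one sample.
    """

    logfc_abs_min: float = 2.0
    p_max: float = 0.01
    fdr_max: float = 0.01
    cpm_min: float = 5.0
    prior_cpm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("logfc_abs_min", "p_max", "fdr_max", "cpm_min", "prior_cpm"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def cpm(counts, lib_sizes):
    """Counts per million: count / library size * 1e6.

    Accepts scalars, arrays, or a DataFrame with per-column library sizes.
    """
    lib = np.asarray(lib_sizes, dtype=float)
    if (lib <= 0).any():
        raise InputError("library size must be positive")
    if isinstance(counts, pd.DataFrame):
        return counts.div(pd.Series(lib_sizes, dtype=float), axis=1) * 1e6
    return np.asarray(counts, dtype=float) / lib * 1e6


def estimate_bcv(
    cm: CountMatrix,
    housekeeping_ids,
    *,
    bcv_override: float | None = None,
    floor: float = 0.01,
    min_genes: int = 10,
    cpm_min: float = 5.0,
) -> DispersionModel:
    """Estimate the BCV from housekeeping genes, or accept an override.

    Housekeeping genes are assumed not to change between the two conditions,
    so their across-sample variation reflects biological noise plus Poisson
    counting noise.  Per gene the squared coefficient of variation of cpm is
    computed; its median across genes is rescaled by the chi-square median
    (with m samples, the per-gene CV^2 under pure noise is approximately the
    total CV^2 times chi2_{m-1}/(m-1), whose median is well below 1, so the
    raw median would be biased low); the Poisson component 1/mean-count is
    then subtracted in quadrature and the result floored at ``floor``.

    With ``bcv_override`` set (e.g. the study value 0.045) the data are
    ignored and the override is returned verbatim.
    """
    if bcv_override is not None:
        return DispersionModel(bcv=float(bcv_override))
    hk = [g for g in housekeeping_ids if g in cm.counts.index]
    sub = cm.counts.loc[hk]
    cpms = cpm(sub, cm.lib_sizes)
    keep = (cpms > cpm_min).any(axis=1)
    sub, cpms = sub[keep], cpms[keep]
    if len(sub) < min_genes:
        raise EstimationError(
            f"need >= {min_genes} housekeeping genes after the cpm filter, got {len(sub)}"
        )
    # housekeeping-anchored median-ratio normalization: composition shifts
    # (e.g. a block of strongly regulated genes changing the effective depth)
    # move every housekeeping gene by the same factor and would otherwise be
    # mistaken for biological variation
    gm = np.exp(np.log(cpms.where(cpms > 0)).mean(axis=1))
    factors = (cpms.div(gm, axis=0)).median(axis=0)
    cpms = cpms.div(factors, axis=1)
    m = cpms.shape[1]
    mean_cpm = cpms.mean(axis=1)
    cv2 = cpms.std(axis=1, ddof=1) ** 2 / mean_cpm**2
    mean_count = sub.mean(axis=1)
    df = m - 1
    correction = stats.chi2.median(df) / df
    total_cv2 = float(cv2.median()) / correction
    bcv2 = total_cv2 - float((1.0 / mean_count).median())
    return DispersionModel(bcv=math.sqrt(max(bcv2, floor**2)))


def _equalized(y1: float, y2: float, lib1: float, lib2: float) -> tuple[int, int]:
    """Scale both counts to the geometric-mean library size, round half-to-even."""
    lib = math.sqrt(lib1 * lib2)
    return int(np.rint(y1 * lib / lib1)), int(np.rint(y2 * lib / lib2))


def _conditional_logpmf(s: int, dispersion: float) -> np.ndarray:
    """log P(y | y + y' = s) for two iid NB(mu=s/2, dispersion) counts.

    At dispersion 0 this is exactly Binomial(s, 1/2).
    """
    k = np.arange(s + 1)
    if dispersion <= 1e-12:  # numerically Poisson: conditional is binomial
        return stats.binom.logpmf(k, s, 0.5)
    mu = s / 2.0
    r = 1.0 / dispersion
    p = r / (r + mu)
    half = stats.nbinom.logpmf(k, r, p)
    logp = half + half[::-1]
    return logp - logsumexp(logp)


def exact_test(y1, y2, lib1=1.0, lib2=1.0, dispersion=0.0) -> float:
    """Two-sided exact conditional NB test for a two-library comparison.

    Counts are first scaled to the common (geometric-mean) library size and
    rounded.  Conditional on the equalized total s, the two-sided p-value is
    the sum of conditional probabilities of all splits whose probability does
    not exceed that of the observed split ("small-p" convention; ties
    included), computed by direct summation over 0..s.
    """
    if y1 < 0 or y2 < 0:
        raise InputError("counts must be nonnegative")
    if dispersion < 0:
        raise InputError("dispersion must be nonnegative")
    if lib1 <= 0 or lib2 <= 0:
        raise InputError("library sizes must be positive")
    y1e, y2e = _equalized(y1, y2, lib1, lib2)
    s = y1e + y2e
    if s == 0:
        return 1.0
    logp = _conditional_logpmf(s, dispersion)
    keep = logp <= logp[y1e] + _TIE_LOG_TOL
    if keep.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def log_fold_change(cpm_treated, cpm_control, prior: float = 0.5):
    """Moderated log2 fold change: log2((cpm_t + prior) / (cpm_c + prior)).

    Positive values mean up in treated relative to control.  The prior (in
    cpm units) keeps the ratio finite when one side is zero.
    """
    if prior <= 0:
        raise InputError("prior must be positive")
    return np.log2((np.asarray(cpm_treated, float) + prior) / (np.asarray(cpm_control, float) + prior))


def call_degs(
    cm: CountMatrix,
    model: DispersionModel,
    filt: DEGFilter = DEGFilter(),
    *,
    treated: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Test every abundant gene and call up/down/ns at the configured thresholds.

    Genes failing the abundance filter (cpm <= cpm_min in both samples) are
    excluded before testing; BH FDR is computed over the tested genes only.
    Returns a DEG table sorted by |logFC| descending with columns gene_id,
    logFC, PValue, FDR, mean_cpm, call.
    """
    if len(cm.samples) != 2:
        raise UnsupportedDesignError(
            f"exactly two samples required (treated vs control), got {len(cm.samples)}"
        )
    if treated is None or control is None:
        control, treated = cm.samples if treated is None and control is None else (control, treated)
    if treated not in cm.samples or control not in cm.samples:
        raise InputError("treated/control labels not found in count matrix")

    cpms = cpm(cm.counts, cm.lib_sizes)
    keep = (cpms > filt.cpm_min).any(axis=1)
    tested = cm.counts[keep]
    cpms = cpms[keep]

    lib_t = float(cm.lib_sizes[treated])
    lib_c = float(cm.lib_sizes[control])
    disp = model.dispersion
    pvals = np.array(
        [
            exact_test(yt, yc, lib_t, lib_c, disp)
            for yt, yc in zip(tested[treated].to_numpy(), tested[control].to_numpy())
        ]
    )
    lfc = log_fold_change(cpms[treated], cpms[control], prior=filt.prior_cpm)
    if len(pvals):
        fdr = multipletests(pvals, method="fdr_bh")[1]
    else:
        fdr = np.array([])

    table = pd.DataFrame(
        {
            "gene_id": tested.index,
            "logFC": np.asarray(lfc, float),
            "PValue": pvals,
            "FDR": fdr,
            "mean_cpm": cpms.mean(axis=1).to_numpy(),
        }
    )
    sig = (table["PValue"] <= filt.p_max) & (table["FDR"] <= filt.fdr_max)
    call = np.full(len(table), "ns", dtype=object)
    call[sig & (table["logFC"] >= filt.logfc_abs_min)] = "up"
    call[sig & (table["logFC"] <= -filt.logfc_abs_min)] = "down"
    table["call"] = call
    table = table.sort_values(
        by=["logFC", "gene_id"], key=lambda s: -s.abs() if s.name == "logFC" else s
    ).reset_index(drop=True)
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
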