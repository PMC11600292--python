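"""Expression normalization.

Implements exclusion-aware TPM (plasma-cell-specific / immunoglobulin
transcripts can be excluded from the per-sample denominator to remove the
bias introduced by variable immunoglobulin transcription), reference-ratio
median size factors computed jointly on circular and linear counts, the
bounded circ-to-linear ratio c/(c+l), and per-sample total circRNA expression.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


def tpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts-per-million for linear features.

    Features flagged ``excluded_from_tpm`` still receive TPM values but do not
    contribute to the per-sample denominator, so the included features of each
    sample sum to exactly 1e6.
    """
    if (m.feature_meta["kind"] != "linear").any():
        raise ValueError("tpm expects linear features only")
    lengths = pd.to_numeric(m.feature_meta["length_bp"]).to_numpy(dtype=float)
    rates = m.values.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    included = ~m.feature_meta["excluded_from_tpm"].astype(bool).to_numpy()
    denom = rates[included].sum(axis=0)
    if (denom == 0).any():
        bad = m.values.columns[denom == 0]
        raise ValueError(f"zero TPM denominator for sample(s): {list(bad)}")
    out = rates / denom[None, :] * 1e6
    return pd.DataFrame(out, index=m.values.index, columns=m.values.columns)


def log2_tpm(tpm_matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if (tpm_matrix.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    if pseudocount <= 0 and (tpm_matrix.to_numpy() == 0).any():
        raise ValueError("pseudocount must be positive when zeros are present")
    return np.log2(tpm_matrix + pseudocount)


def size_factors(
    m: Union[ExpressionMatrix, pd.DataFrame],
    rescale: bool = True,
    pseudo_reference: bool = False,
) -> pd.Series:
    """Reference-ratio median size factors (Anders–Huber).

    s_j = median over all-positive features i of count_ij / geomean_i. With
    ``pseudo_reference=True`` the geometric mean per feature is taken over its
    positive counts only and the median over features with a positive count in
    the sample, for sparse matrices with no all-positive feature. Factors are
    rescaled to geometric mean 1 unless ``rescale=False``.
    """
    counts = m.values if isinstance(m, ExpressionMatrix) else m
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty count matrix")
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any() and not pseudo_reference:
        raise ValueError(
            "no feature has strictly positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    if pseudo_reference and not all_pos.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(arr > 0, arr / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        ref = arr[all_pos]
        geo = np.exp(np.mean(np.log(ref), axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("degenerate size factors; check input counts")
    if rescale:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def combined_size_factors(
    circ_counts: pd.DataFrame, linear_counts: pd.DataFrame, **kwargs
) -> pd.Series:
    """Size factors from the stacked circular + linear count matrix."""
    if not circ_counts.columns.equals(linear_counts.columns):
        linear_counts = linear_counts[circ_counts.columns]
    stacked = pd.concat([circ_counts, linear_counts], axis=0)
    if not stacked.index.is_unique:
        stacked.index = [f"r{i}" for i in range(len(stacked))]
    return size_factors(stacked, **kwargs)


def circ_linear_ratio(circ_reads, linear_reads, form: str = "bounded"):
    """circ-to-linear ratio.

    ``bounded`` (default): c/(c+l) in [0, 1], NaN when both are zero; a value
    above 0.5 means the circle out-expresses its host. ``raw``: (c+0.5)/(l+0.5).
    Accepts scalars or arrays.
    """
    c = np.asarray(circ_reads, dtype=float)
    l = np.asarray(linear_reads, dtype=float)
    if (c < 0).any() or (l < 0).any():
        raise ValueError("read counts must be non-negative")
    if form == "bounded":
        total = c + l
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, c / np.where(total > 0, total, 1.0), np.nan)
    elif form == "raw":
        out = (c + 0.5) / (l + 0.5)
    else:
        raise ValueError(f"unknown form {form!r}")
    if out.ndim == 0:
        return float(out)
    return out


def total_circ_expression(
    circ_counts: pd.DataFrame,
    s: pd.Series,
    method: str = "sum_normalized",
) -> pd.Series:
    """Per-sample circRNA burden.

    ``sum_normalized`` (default): sum of size-factor-normalized consensus BSJ
    counts. ``unique_count``: number of distinct circRNAs with a nonzero count.
    """
    if not set(circ_counts.columns) == set(s.index):
        raise ValueError("samples of counts and size factors do not match")
    s = s[circ_counts.columns]
    if method == "sum_normalized":
        out = circ_counts.sum(axis=0) / s
    elif method == "unique_count":
        out = (circ_counts > 0).sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    out.name = "total_circ_expression"
    return out
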