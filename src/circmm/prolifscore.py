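"""Gene-set proliferative index scoring and patient stratification.

Three proliferation gene signatures are shipped as an editable data file:
a 12-gene set (Bergsagel-style), an 11-gene set (Shaughnessy-style) and a
50-gene plasma-cell-proliferation set (Hose-style). The latter is specific to
plasma cells and is gated to purified plasma-cell cohorts. Index scores are
arithmetic means of log2(TPM) over the signature genes present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EXPECTED_SIZES = {"bergsagel": 12, "shaughnessy": 11, "hose": 50}


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name}: duplicate genes")
        expected = EXPECTED_SIZES.get(self.name)
        if expected is not None and len(self.genes) != expected:
            raise ValueError(
                f"signature {self.name}: expected {expected} genes, got {len(self.genes)}"
            )


def load_signatures(path: Optional[Path | str] = None) -> dict[str, GeneSignature]:
    """Load signatures from a TSV (signature_name, gene_id)."""
    if path is None:
        source = resources.files("circmm").joinpath("data/signatures.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    out = {}
    for name, group in table.groupby("signature_name"):
        out[name] = GeneSignature(name=name, genes=tuple(group["gene_id"]))
    return out


def prolif_index(
    log2tpm: pd.DataFrame,
    sig: GeneSignature,
    cohort_mode: Optional[str] = None,
    force: bool = False,
) -> pd.Series:
    """Per-sample proliferative index: mean log2(TPM) over signature genes.

    At least 90% of the signature genes must be present; missing genes are
    logged and skipped. The 50-gene plasma-cell signature refuses to run on a
    whole bone-marrow cohort unless ``force=True``.
    """
    if sig.name == "hose" and cohort_mode == "whole_bm" and not force:
        raise ValueError(
            "the hose signature is plasma-cell specific and is not applied "
            "to whole_bm cohorts (pass force=True to override)"
        )
    present = [g for g in sig.genes if g in log2tpm.index]
    missing = [g for g in sig.genes if g not in log2tpm.index]
    if len(present) < 0.9 * len(sig.genes):
        raise ValueError(f"signature {sig.name}: too many genes missing: {missing}")
    if missing:
        log.warning("signature %s: %d gene(s) missing, using %d: %s",
                    sig.name, len(missing), len(present), missing)
    score = log2tpm.loc[present].mean(axis=0)
    score.name = f"{sig.name}_index"
    return score


def turnover_ratio(
    tpm_matrix: pd.DataFrame,
    gene_num: str = "BCL2",
    gene_den: str = "MKI67",
    pseudocount: float = 1.0,
) -> pd.Series:
    """BCL2/MKI67-style turnover ratio in TPM units; higher = lower turnover."""
    for gene in (gene_num, gene_den):
        if gene not in tpm_matrix.index:
            raise ValueError(f"gene {gene} not present in expression matrix")
    ratio = (tpm_matrix.loc[gene_num] + pseudocount) / (tpm_matrix.loc[gene_den] + pseudocount)
    ratio.name = f"{gene_num}_{gene_den}_ratio"
    return ratio


def stratify_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> "high", otherwise "low"."""
    if len(scores) < 4:
        raise ValueError("median stratification needs at least 4 samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical: degenerate stratification")
    cutoff = scores.median()
    labels = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)
    labels.name = "stratum"
    return labels


def stratify_reference(scores: pd.Series, ref_scores: pd.Series) -> pd.Series:
    """Reference split at median(ref) + 2*sd(ref) (sample sd, n-1)."""
    if len(ref_scores) < 3:
        raise ValueError("reference stratification needs at least 3 reference samples")
    cutoff = ref_scores.median() + 2.0 * ref_scores.std(ddof=1)
    labels = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)
    labels.name = "stratum"
    return labels
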