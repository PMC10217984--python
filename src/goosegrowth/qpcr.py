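"""Relative expression by the comparative-Ct (2^-ΔΔCt) method.

Fold change of a target gene is computed against a reference
(housekeeping) gene such as GAPDH and a calibrator sample:
``ΔCt = Ct_target − Ct_reference`` within a sample,
``ΔΔCt = ΔCt_sample − ΔCt_calibrator``, and the fold change is
``2^−ΔΔCt``.  Technical replicates of a (sample, gene) pair are
averaged on the Ct scale before any differencing, the standard
convention.  Amplification efficiency is fixed at 2 per cycle;
efficiency-corrected models are out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "mean_ct",
    "fold_change_table",
    "read_ct_csv",
]

_CT_COLUMNS = ("sample", "gene", "replicate", "ct")


def relative_expression(target_ct, reference_ct, calibrator_delta_ct=0.0):
    """Fold change ``2^-((target_ct - reference_ct) - calibrator_delta_ct)``.

    All arguments are mean Ct values (cycles); scalars or arrays.
    ΔΔCt = 0 gives fold change 1; each extra cycle of the target halves
    the fold change.
    """
    target_ct = np.asarray(target_ct, dtype=float)
    if not np.all(np.isfinite(target_ct)) or not np.all(
        np.isfinite(np.asarray(reference_ct, dtype=float))
    ):
        raise ValueError("Ct values must be finite")
    ddct = (target_ct - reference_ct) - calibrator_delta_ct
    fold = 2.0 ** (-ddct)
    return float(fold) if np.ndim(fold) == 0 else fold


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path)
    missing = set(_CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct CSV is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["ct"].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite numbers")
    return df


def mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean Ct per (sample, gene) across replicates."""
    return ct.groupby(["sample", "gene"], as_index=False)["ct"].mean()


def fold_change_table(
    ct: pd.DataFrame, reference_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Per-gene fold changes of every sample against a calibrator sample.

    Returns columns sample, gene, delta_ct, ddct, fold_change for every
    target gene (the reference gene itself is excluded).
    """
    means = mean_ct(ct)
    ref = means[means["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not found")
    targets = means[means["gene"] != reference_gene].copy()
    if calibrator_sample not in set(means["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not found")
    targets["delta_ct"] = targets["ct"] - targets["sample"].map(ref).to_numpy()
    if targets["delta_ct"].isna().any():
        bad = targets.loc[targets["delta_ct"].isna(), "sample"].unique()
        raise ValueError(f"samples missing the reference gene: {list(bad)}")
    cal = targets[targets["sample"] == calibrator_sample].set_index("gene")["delta_ct"]
    targets["ddct"] = targets["delta_ct"] - targets["gene"].map(cal).to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "gene", "delta_ct", "ddct", "fold_change"]].reset_index(drop=True)
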