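"""Column-level amino-acid diversity: entropy, BLOSUM80 similarity, distance.

Three measures of residue variability at alignment columns, applied to the
ten key binding-cavity positions of each subgroup:

* Shannon entropy H = -sum p(x) log2 p(x) in bits (0 <= H <= log2 20 ~ 4.32);
* the Karlin-Brocchieri similarity C(X) = mean over sequence pairs (r < s)
  of m(x,y) / sqrt(m(x,x) m(y,y)), with m the BLOSUM80 substitution score;
* D_key, the mean pairwise JTT-ML distance over the key-column
  mini-alignment (reported alongside -log10 D_key).

Regressions of these measures against log10 <omega_key> quantify how much
of the spread in selection pressure is explained by residue variability.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .phylogeny import jtt_ml_distance

MAX_ENTROPY_BITS = float(np.log2(20))

_BLOSUM80 = None


class DiversityError(ValueError):
    pass


def blosum80():
    global _BLOSUM80
    if _BLOSUM80 is None:
        _BLOSUM80 = substitution_matrices.load("BLOSUM80")
    return _BLOSUM80


def shannon_entropy(column, count_gaps: bool = False) -> float:
    """Plug-in Shannon entropy (bits) of the residues at one column.

    Gaps are excluded from the frequencies by default; with
    ``count_gaps=True`` the gap is a 21st symbol. An all-gap column is
    undefined and returns NaN.
    """
    residues = [r for r in column if count_gaps or r != "-"]
    if not residues:
        return np.nan
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def karlin_similarity(column, matrix=None) -> float:
    """Karlin-Brocchieri normalized substitution score of one column.

    Averages M(x, y) = m(x, y) / sqrt(m(x, x) m(y, y)) over all unordered
    pairs of non-gap residues. Needs at least two non-gap residues; unknown
    residues raise DiversityError.
    """
    mat = matrix if matrix is not None else blosum80()
    residues = [r for r in column if r != "-"]
    if len(residues) < 2:
        raise DiversityError("need >= 2 non-gap residues")
    alphabet = set(mat.alphabet)
    for r in residues:
        if r not in alphabet:
            raise DiversityError(f"residue {r!r} absent from substitution table")
    total = 0.0
    n_pairs = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            x, y = residues[i], residues[j]
            total += mat[x, y] / np.sqrt(mat[x, x] * mat[y, y])
            n_pairs += 1
    return total / n_pairs


def column_distance(
    aa_alignment, key_columns: list[int], per_column: bool = False
) -> tuple[float, float]:
    """(D_key, -log10 D_key) from JTT-ML distances on the key columns.

    Default mode builds the concatenated key-column mini-alignment and
    averages the pairwise JTT-ML distances; ``per_column=True`` instead
    averages single-column distances over the key columns. D_key = 0
    (identical residues) yields an infinite -log10, flagged by the caller.
    """
    if aa_alignment.n_sequences < 2:
        raise DiversityError("need >= 2 sequences")
    idx = [int(c) - 1 for c in key_columns]
    if not idx:
        raise DiversityError("no key columns")
    sub = aa_alignment.residues[:, idx]
    S = sub.shape[0]

    def mean_pairwise(block: np.ndarray) -> float:
        vals = []
        for i in range(S):
            for j in range(i + 1, S):
                vals.append(jtt_ml_distance(block[i], block[j]))
        return float(np.mean(vals))

    if per_column:
        d = float(np.mean([mean_pairwise(sub[:, [k]]) for k in range(sub.shape[1])]))
    else:
        d = mean_pairwise(sub)
    neg_log = -np.log10(d) if d > 0 else np.inf
    return d, float(neg_log)


def diversity_profile(aa_alignment, key_columns: list[int]) -> dict:
    """Per-column entropy and similarity plus key-column averages."""
    L = aa_alignment.column_count
    H = np.array([shannon_entropy(aa_alignment.column(c)) for c in range(1, L + 1)])
    key_idx = [int(c) - 1 for c in key_columns]
    C_key = np.array(
        [karlin_similarity(aa_alignment.column(c)) for c in key_columns]
    )
    d_key, neg_log_d = column_distance(aa_alignment, key_columns)
    return {
        "entropy": H,
        "entropy_key_mean": float(np.nanmean(H[key_idx])),
        "karlin_key": C_key,
        "blo80_key_mean": float(np.mean(C_key)),
        "D_key": d_key,
        "neg_log10_D_key": neg_log_d,
    }


def diversity_vs_selection(
    report: pd.DataFrame,
    measure: str,
    omega_column: str = "omega_key_mean",
    admission_flags: dict[str, set] | None = None,
    restrict_below: float = 0.1,
) -> dict:
    """OLS of a diversity measure against log10 <omega_key> across subgroups.

    Subgroups flagged "N" (inadmissible under max dN < 1) are excluded. The
    regression is repeated restricted to <omega_key> < ``restrict_below``
    (the strong-negative-selection range), where correlations weaken.
    """
    df = report.copy()
    if admission_flags:
        keep = [
            sg
            for sg in df["subgroup_id"]
            if "N" not in admission_flags.get(str(sg), set())
        ]
        df = df[df["subgroup_id"].isin(keep)]
    df = df[(df[omega_column] > 0) & np.isfinite(df[measure])]
    if len(df) < 3:
        raise DiversityError("need >= 3 subgroups after filtering")
    x = np.log10(df[omega_column].to_numpy(dtype=float))
    y = df[measure].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    out = {
        "measure": measure,
        "r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "slope": float(res.slope),
        "n": int(len(df)),
    }
    sub = df[df[omega_column] < restrict_below]
    if len(sub) >= 3:
        xs = np.log10(sub[omega_column].to_numpy(dtype=float))
        ys = sub[measure].to_numpy(dtype=float)
        r2 = stats.linregress(xs, ys)
        out["restricted"] = {
            "r": float(r2.rvalue),
            "p_value": float(r2.pvalue),
            "n": int(len(sub)),
            "threshold": restrict_below,
        }
    return out
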