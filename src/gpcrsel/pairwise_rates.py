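"""Nei-Gojobori pairwise dN/dS and the subgroup admission filter.

Synonymous and nonsynonymous sites are counted per codon by splitting each
of the three positions among its single-nucleotide alternatives; differences
between codon pairs are averaged over all mutational pathways. Proportions
are corrected with the Jukes-Cantor formula. Subgroups are admitted when the
maximum pairwise dN stays below 1 (iteratively dropping outliers), with a
secondary max dS < 3 flag.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._codons import (
    CODON_INDEX,
    GAP_CODON,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    translate_codon,
)

NUCS = "ACGT"


class RateError(ValueError):
    pass


def ng_site_counts(codon: str, stop_mutations: str = "nonsynonymous") -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one sense codon.

    Each codon position contributes one site, split by the fraction of its
    three single-nucleotide alternatives that are synonymous. Mutations that
    create stop codons are counted as nonsynonymous by default
    (``stop_mutations="nonsynonymous"``, so s + n = 3 exactly) or excluded
    from the alternatives (``"excluded"``, the other common convention).
    """
    if codon in STOP_CODONS:
        raise RateError(f"stop codon {codon}")
    if codon not in CODON_INDEX:
        raise RateError(f"invalid codon {codon!r}")
    aa = translate_codon(codon)
    s = 0.0
    n = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                if stop_mutations == "excluded":
                    continue
                considered += 1  # counts as a nonsynonymous alternative
                continue
            considered += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if considered == 0:
            n += 1.0
            continue
        s += syn / considered
        n += 1.0 - syn / considered
    return s, n


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two codons.

    Codon pairs differing at k positions are resolved by averaging over the
    k! orderings of the single changes; pathways that pass through a stop
    codon are excluded. If every pathway is blocked (cannot happen between
    sense codons for k <= 3, but guarded anyway), stop-traversing pathways
    are counted with their non-stop steps.
    """
    diffs = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        syn = 0
        nonsyn = 0
        current = codon_a
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (valid if ok else blocked).append((syn, nonsyn))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise RateError("negative proportion")
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng_pairwise(
    seq_a: list[str],
    seq_b: list[str],
    stop_mutations: str = "nonsynonymous",
) -> dict:
    """Nei-Gojobori dN/dS between two gapless codon sequences.

    Site totals are averaged over the two sequences; multi-step codon pairs
    are pathway-averaged. Returns a dict with pN, pS, dN, dS (NaN where the
    Jukes-Cantor correction is undefined, i.e. p >= 3/4) and saturation
    flags.
    """
    if len(seq_a) != len(seq_b):
        raise RateError(f"length mismatch {len(seq_a)} vs {len(seq_b)}")
    pairs = [
        (a, b) for a, b in zip(seq_a, seq_b) if a != GAP_CODON and b != GAP_CODON
    ]
    if not pairs:
        raise RateError("no comparable (gap-free) codon columns")
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    for a, b in pairs:
        sa, na = ng_site_counts(a, stop_mutations)
        sb, nb = ng_site_counts(b, stop_mutations)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = _pathway_differences(a, b)
        Sd += sd
        Nd += nd
    S = 0.5 * (S_a + S_b)
    N = 0.5 * (N_a + N_b)
    pS = Sd / S if S > 0 else np.nan
    pN = Nd / N if N > 0 else np.nan
    dS = jukes_cantor(pS) if np.isfinite(pS) else np.nan
    dN = jukes_cantor(pN) if np.isfinite(pN) else np.nan
    return {
        "pN": pN,
        "pS": pS,
        "dN": dN,
        "dS": dS,
        "N_sites": N,
        "S_sites": S,
        "saturated_S": bool(np.isfinite(pS) and pS >= 0.75),
        "saturated_N": bool(np.isfinite(pN) and pN >= 0.75),
        "codons_compared": len(pairs),
    }


@dataclass
class PairwiseRateTable:
    """Symmetric pairwise dN/dS matrices over subgroup members."""

    labels: list[str]
    dN: np.ndarray
    dS: np.ndarray
    flags: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def max_dN(self) -> float:
        off = self.dN[~np.eye(len(self.labels), dtype=bool)]
        return float(np.nanmax(off)) if off.size else 0.0

    def max_dS(self) -> float:
        off = self.dS[~np.eye(len(self.labels), dtype=bool)]
        finite = off[np.isfinite(off)]
        return float(np.max(finite)) if finite.size else np.inf

    def any_saturated_S(self) -> bool:
        n = len(self.labels)
        return any(
            "saturated_S" in self.flags.get((self.labels[i], self.labels[j]), set())
            for i in range(n)
            for j in range(i + 1, n)
        )

    def drop(self, label: str) -> "PairwiseRateTable":
        keep = [i for i, l in enumerate(self.labels) if l != label]
        labels = [self.labels[i] for i in keep]
        idx = np.ix_(keep, keep)
        flags = {
            k: v
            for k, v in self.flags.items()
            if label not in k
        }
        return PairwiseRateTable(labels, self.dN[idx], self.dS[idx], flags)


def pairwise_rate_table(
    alignment, stop_mutations: str = "nonsynonymous"
) -> PairwiseRateTable:
    """All-pairs Nei-Gojobori table for a CodonAlignment.

    Codon columns with a gap in either member of a pair are deleted pairwise
    before counting.
    """
    labels = list(alignment.labels)
    S = len(labels)
    dN = np.zeros((S, S))
    dS = np.zeros((S, S))
    flags: dict[tuple[str, str], set[str]] = {}
    for i in range(S):
        for j in range(i + 1, S):
            res = ng_pairwise(
                list(alignment.codons[i]),
                list(alignment.codons[j]),
                stop_mutations=stop_mutations,
            )
            dN[i, j] = dN[j, i] = res["dN"]
            dS[i, j] = dS[j, i] = res["dS"]
            f = set()
            if res["saturated_N"] or not np.isfinite(res["dN"]):
                f.add("saturated_N")
            if res["saturated_S"] or not np.isfinite(res["dS"]):
                f.add("saturated_S")
            if f:
                flags[(labels[i], labels[j])] = f
    return PairwiseRateTable(labels, dN, dS, flags)


@dataclass
class AdmissionReport:
    """Outcome of the max(dN) < 1 refinement with max(dS) < 3 flagging."""

    passed: bool
    flags: set[str]
    retained_labels: list[str]
    removed_labels: list[str]
    max_dN: float
    max_dS: float
    offending_pairs: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "flags": sorted(self.flags),
            "retained_labels": self.retained_labels,
            "removed_labels": self.removed_labels,
            "max_dN": self.max_dN,
            "max_dS": None if not np.isfinite(self.max_dS) else self.max_dS,
            "offending_pairs": [list(p) for p in self.offending_pairs],
        }


def subgroup_admission(
    table: PairwiseRateTable,
    dn_threshold: float = 1.0,
    ds_threshold: float = 3.0,
    min_members: int = 3,
    criterion: str = "max",
) -> AdmissionReport:
    """Apply the max(dN) < 1 admission rule with iterative outlier removal.

    While the dN condition fails, the member with the largest mean dN to all
    others is removed (ties broken by label order) until the condition holds
    or fewer than ``min_members`` remain; an irreducible subgroup is flagged
    "N". A subgroup whose maximum dS reaches ``ds_threshold`` (or with a
    saturated synonymous proportion) is retained but flagged "S".
    ``criterion="mean"`` tests the mean-over-pairs dN instead of the maximum.
    """
    if len(table.labels) < min_members:
        raise RateError(f"admission needs >= {min_members} members")

    def stat(t: PairwiseRateTable) -> float:
        off = t.dN[np.triu_indices(len(t.labels), k=1)]
        off = off[np.isfinite(off)]
        if off.size == 0:
            return np.inf  # all nonsynonymous distances saturated
        return float(np.max(off)) if criterion == "max" else float(np.mean(off))

    removed: list[str] = []
    current = table
    while stat(current) >= dn_threshold and len(current.labels) > min_members:
        means = np.nanmean(
            np.where(np.eye(len(current.labels), dtype=bool), np.nan, current.dN),
            axis=1,
        )
        worst = int(np.nanargmax(means))
        removed.append(current.labels[worst])
        current = current.drop(current.labels[worst])

    flags: set[str] = set()
    passed = stat(current) < dn_threshold
    if not passed:
        flags.add("N")
    max_ds = current.max_dS()
    if (max_ds >= ds_threshold) or current.any_saturated_S():
        flags.add("S")
    n = len(current.labels)
    offending = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(current.dN[i, j]) and current.dN[i, j] >= dn_threshold:
                offending.append((current.labels[i], current.labels[j]))
    return AdmissionReport(
        passed=passed,
        flags=flags,
        retained_labels=list(current.labels),
        removed_labels=removed,
        max_dN=stat(current),
        max_dS=max_ds,
        offending_pairs=offending,
    )
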