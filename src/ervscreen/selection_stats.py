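"""Nei-Gojobori dN/dS estimation and the codon-based Z-test of neutrality.

The method counts, for each codon, the fraction of single-nucleotide
changes that are synonymous (synonymous "sites"), averages synonymous and
nonsynonymous step counts over all mutational pathways between a codon
pair (excluding pathways through stop codons), converts the resulting
proportions to rates with the Jukes-Cantor correction, and tests
H0: dN = dS with Z = (dS - dN)/sqrt(Var(dS) + Var(dN)), the variances
estimated by bootstrap over codon columns.

Site counting excludes mutations to stop codons from the per-position
denominator (fraction_syn = syn / (3 - stops)), and nonsynonymous sites
are the complement (n = 3 - s), so S + N = 3L exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .genome_io import STOP_CODONS, translate

__all__ = [
    "CodonPairAlignment",
    "SelectionResult",
    "count_sites",
    "count_differences",
    "nei_gojobori",
    "z_test_neutrality",
    "percent_identity",
    "build_codon_alignment",
    "analyze_pair",
]

_BASES = "ACGT"
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(_BASES, repeat=3)) if c not in STOP_CODONS
)


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return translate(codon)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    Per position, fraction_syn = synonymous alternatives / (3 - stop
    alternatives); s sums the three fractions and n = 3 - s.
    """
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        stops = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                stops += 1
            elif _aa(mut) == aa0:
                syn += 1
        denom = 3 - stops
        if denom > 0:
            s += syn / denom
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (sd, nd).

    For k differing positions, every ordering of the k single-nucleotide
    steps is a pathway; pathways whose intermediate codons are stops are
    excluded from the average (if all are excluded, the unweighted average
    over all pathways is used). sd + nd == k.
    """
    for c in (codon_a, codon_b):
        if len(c) != 3 or any(b not in _BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} in difference count")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = 0
        nonsyn = 0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                # still count the step type for the fallback average
                nonsyn += 1
            elif _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not through_stop:
            valid.append((syn, nonsyn))
    pool = valid if valid else all_paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


@dataclass
class CodonPairAlignment:
    """Gap-free, in-frame codon alignment of one cross-species ORF pair."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b) or not self.codons_a:
            raise ValueError("codon lists must be equal-length and non-empty")
        for c in itertools.chain(self.codons_a, self.codons_b):
            if len(c) != 3 or any(b not in _BASES for b in c):
                raise ValueError(f"invalid codon {c!r}")
            if c in STOP_CODONS:
                raise ValueError("stop codon in codon alignment")

    @classmethod
    def from_nt(cls, nt_a: str, nt_b: str) -> "CodonPairAlignment":
        if len(nt_a) != len(nt_b) or len(nt_a) % 3:
            raise ValueError("sequences must be equal length, codon multiple")
        return cls(
            [nt_a[i : i + 3] for i in range(0, len(nt_a), 3)],
            [nt_b[i : i + 3] for i in range(0, len(nt_b), 3)],
        )

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass
class SelectionResult:
    """dN/dS estimates and neutrality test for one ORF pair."""

    n_codons: int
    S_sites: float
    N_sites: float
    sd: float
    nd: float
    pS: float
    pN: float
    dS: float  # nan when the JC correction is undefined (pS >= 3/4)
    dN: float
    percent_identity: float
    var_dS: float = float("nan")
    var_dN: float = float("nan")
    Z: float = float("nan")
    p_value: float = float("nan")
    note: str = ""

    @property
    def dnds(self) -> float:
        if not np.isfinite(self.dS) or self.dS == 0:
            return float("nan")
        return self.dN / self.dS


def _jc(p: np.ndarray | float):
    """Jukes-Cantor correction, nan where p >= 3/4."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * np.minimum(p, 0.749999999)), np.nan)
    d = np.where(p < 0.75, d, np.nan)
    return d if d.shape else float(d)


def _per_codon_arrays(aln: CodonPairAlignment):
    sa = np.empty(len(aln))
    sb = np.empty(len(aln))
    sd = np.empty(len(aln))
    nd = np.empty(len(aln))
    for i, (ca, cb) in enumerate(zip(aln.codons_a, aln.codons_b)):
        sa[i] = count_sites(ca)[0]
        sb[i] = count_sites(cb)[0]
        sd[i], nd[i] = count_differences(ca, cb)
    return sa, sb, sd, nd


def nei_gojobori(aln: CodonPairAlignment) -> SelectionResult:
    """Estimate dN and dS for a codon pair alignment (NG86 with JC)."""
    L = len(aln)
    sa, sb, sdv, ndv = _per_codon_arrays(aln)
    S = (sa.sum() + sb.sum()) / 2.0
    N = 3.0 * L - S
    sd_tot = float(sdv.sum())
    nd_tot = float(ndv.sum())
    note = ""
    if S > 0:
        pS = sd_tot / S
        dS = _jc(pS)
    else:
        pS, dS = float("nan"), float("nan")
        note = "S=0: dS undefined"
    pN = nd_tot / N if N > 0 else float("nan")
    dN = _jc(pN) if N > 0 else float("nan")
    if np.isnan(dS) and not note:
        note = "pS >= 3/4: JC correction undefined for dS"
    aa_a = "".join(_aa(c) for c in aln.codons_a)
    aa_b = "".join(_aa(c) for c in aln.codons_b)
    return SelectionResult(
        n_codons=L,
        S_sites=S,
        N_sites=N,
        sd=sd_tot,
        nd=nd_tot,
        pS=float(pS),
        pN=float(pN),
        dS=float(dS),
        dN=float(dN),
        percent_identity=percent_identity(aa_a, aa_b),
        note=note,
    )


def z_test_neutrality(
    aln: CodonPairAlignment,
    alternative: str = "purifying",
    n_boot: int = 1000,
    seed: int = 0,
    variance: str = "difference",
) -> SelectionResult:
    """Codon-based Z-test of neutrality with bootstrap variances.

    Codon columns are resampled with replacement n_boot times. By default
    the standard error is the bootstrap standard deviation of the
    difference dS - dN (variance="difference"), so the positive
    covariance between the two replicate estimates is accounted for;
    variance="independent" uses sqrt(Var(dS) + Var(dN)) instead, which is
    conservative because it ignores that covariance. For the
    ``purifying`` alternative Z = (dS - dN)/SE and the p-value is the
    upper normal tail; ``positive`` flips the sign; ``neutral2sided`` is
    two-tailed.
    """
    if alternative not in {"purifying", "positive", "neutral2sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if variance not in {"difference", "independent"}:
        raise ValueError(f"unknown variance method {variance!r}")
    res = nei_gojobori(aln)
    L = res.n_codons
    sa, sb, sdv, ndv = _per_codon_arrays(aln)
    if res.sd == 0 and res.nd == 0:
        # identical sequences: no information against neutrality
        res.Z = 0.0
        res.p_value = 1.0
        res.var_dS = 0.0
        res.var_dN = 0.0
        res.note = (res.note + "; " if res.note else "") + "identical sequences"
        return res
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    S_r = (sa[idx].sum(axis=1) + sb[idx].sum(axis=1)) / 2.0
    N_r = 3.0 * L - S_r
    with np.errstate(invalid="ignore", divide="ignore"):
        pS_r = np.where(S_r > 0, sdv[idx].sum(axis=1) / np.maximum(S_r, 1e-300), np.nan)
        pN_r = np.where(N_r > 0, ndv[idx].sum(axis=1) / np.maximum(N_r, 1e-300), np.nan)
    dS_r = _jc(pS_r)
    dN_r = _jc(pN_r)
    res.var_dS = float(np.nanvar(dS_r, ddof=1))
    res.var_dN = float(np.nanvar(dN_r, ddof=1))
    if variance == "difference":
        se = float(np.nanstd(dS_r - dN_r, ddof=1))
    else:
        se = float(np.sqrt(res.var_dS + res.var_dN))
    if not np.isfinite(se) or se == 0:
        res.Z = float("nan")
        res.p_value = float("nan")
        res.note = (res.note + "; " if res.note else "") + "zero bootstrap variance"
        return res
    if not (np.isfinite(res.dS) and np.isfinite(res.dN)):
        res.Z = float("nan")
        res.p_value = float("nan")
        res.note = (res.note + "; " if res.note else "") + "dS or dN undefined"
        return res
    if alternative == "purifying":
        res.Z = (res.dS - res.dN) / se
        res.p_value = float(norm.sf(res.Z))
    elif alternative == "positive":
        res.Z = (res.dN - res.dS) / se
        res.p_value = float(norm.sf(res.Z))
    else:
        res.Z = (res.dN - res.dS) / se
        res.p_value = float(2.0 * norm.sf(abs(res.Z)))
    return res


def percent_identity(aa_a: str, aa_b: str) -> float:
    """Percent identical positions over the alignment length.

    Columns gapped in both sequences are dropped first; a gap opposite a
    residue counts in the denominator but never as an identity.
    """
    if len(aa_a) != len(aa_b):
        raise ValueError("aligned sequences must be equal length")
    cols = [(x, y) for x, y in zip(aa_a, aa_b) if not (x == "-" and y == "-")]
    if not cols:
        raise ValueError("alignment has no non-gap columns")
    ident = sum(1 for x, y in cols if x == y and x != "-")
    return 100.0 * ident / len(cols)


def build_codon_alignment(nt_a: str, nt_b: str) -> CodonPairAlignment:
    """Codon-align two in-frame coding sequences via their peptides.

    Peptides are globally aligned (BLOSUM62, gap open 11 / extend 1),
    codons are threaded back through the peptide alignment, and gap
    columns are dropped.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if len(nt_a) % 3 or len(nt_b) % 3:
        raise ValueError("coding sequences must be codon multiples")
    aa_a, aa_b = translate(nt_a), translate(nt_b)
    if aa_a.endswith("*"):
        aa_a, nt_a = aa_a[:-1], nt_a[:-3]
    if aa_b.endswith("*"):
        aa_b, nt_b = aa_b[:-1], nt_b[:-3]
    if "*" in aa_a or "*" in aa_b:
        raise ValueError("internal stop codon in coding sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aln = aligner.align(aa_a, aa_b)[0]
    codons_a: list[str] = []
    codons_b: list[str] = []
    for (a_blk, b_blk) in zip(*aln.aligned):
        for off in range(a_blk[1] - a_blk[0]):
            ia = (a_blk[0] + off) * 3
            ib = (b_blk[0] + off) * 3
            ca, cb = nt_a[ia : ia + 3], nt_b[ib : ib + 3]
            if "N" in ca or "N" in cb:
                continue
            codons_a.append(ca)
            codons_b.append(cb)
    return CodonPairAlignment(codons_a, codons_b)


def analyze_pair(
    nt_a: str,
    nt_b: str,
    n_boot: int = 1000,
    seed: int = 0,
    alternative: str = "purifying",
) -> SelectionResult:
    """Full per-pair analysis: codon-align then NG86 + Z-test."""
    aln = build_codon_alignment(nt_a, nt_b)
    return z_test_neutrality(aln, alternative=alternative, n_boot=n_boot, seed=seed)
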