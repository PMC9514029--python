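"""Profile HMMs for retroviral protein domains: build, scan, calibrate.

The model is a simplified Plan7-style local profile: match states with
position-specific emissions, insert states emitting the background, and
delete states, with uniform entry into any match state and free exit from
any match state. Scoring is log-odds (bits) against the background, and
the maximal-scoring local alignment is found by Viterbi. E-values come
from a Gumbel null fitted (method of moments) to scores of random
background peptides.

A domain hit at E < 1e-5 against a retroviral seed profile marks an ORF
as ERV-derived for the downstream screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_io import SeqRecord

__all__ = [
    "ProfileHMM",
    "DomainHit",
    "CalibrationError",
    "build_profile",
    "viterbi_local",
    "calibrate",
    "fit_gumbel",
    "gumbel_tail",
    "scan",
    "save_profiles",
    "load_profiles",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# transition kinds, all out of node j (into node j+1 where applicable)
_TRANS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

_EULER_GAMMA = 0.5772156649015329


class CalibrationError(RuntimeError):
    pass


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (M, 20) rows summing to 1
    background: np.ndarray  # (20,)
    transitions: dict  # kind -> (M-1,) probability arrays
    insert_emissions: np.ndarray = None  # (20,), defaults to background
    calibration: tuple | None = None  # (lambda, mu) of the Gumbel null

    def __post_init__(self) -> None:
        if self.insert_emissions is None:
            self.insert_emissions = self.background
        M = self.match_emissions.shape[0]
        if M < 1:
            raise ValueError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        for grp in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            if M > 1:
                tot = sum(self.transitions[k] for k in grp)
                if not np.allclose(tot, 1.0, atol=1e-9):
                    raise ValueError(f"transition group {grp} must sum to 1")
        # cached bit scores
        self._em_bits = np.zeros((M, 21))
        self._em_bits[:, :20] = np.log2(self.match_emissions / self.background)
        self._t_bits = {
            k: (np.log2(self.transitions[k]) if M > 1 else np.zeros(0)) for k in _TRANS
        }
        self._entry_bits = -math.log2(M)

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class DomainHit:
    profile_name: str
    seq_id: str
    seq_start: int  # 1-based inclusive peptide span
    seq_end: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.seq_start > self.seq_end:
            raise ValueError("seq_start > seq_end")
        if self.evalue < 0:
            raise ValueError("negative E-value")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(a, 20) for a in seq), dtype=np.int64, count=len(seq))


def build_profile(
    seed_records: Sequence[SeqRecord], pseudocount: float = 1.0, name: str = "profile"
) -> ProfileHMM:
    """Build a profile from an aligned set of peptides.

    Columns with >= 50% residues become match states; others are treated as
    insertions relative to the profile. Emissions are Laplace-smoothed
    column frequencies; transitions are smoothed counts of the per-sequence
    state paths (match residue -> M, match gap -> D, insert residue -> I).
    """
    if not seed_records:
        raise ValueError("empty seed alignment")
    ncol = len(seed_records[0].seq)
    if ncol == 0:
        raise ValueError("seed alignment has zero columns")
    if any(len(r.seq) != ncol for r in seed_records):
        raise ValueError("seed sequences are not aligned (unequal lengths)")
    rows = [r.seq.upper() for r in seed_records]
    nseq = len(rows)
    occupancy = [sum(1 for r in rows if r[c] != "-") for c in range(ncol)]
    match_cols = [c for c in range(ncol) if occupancy[c] * 2 >= nseq]
    M = len(match_cols)
    if M == 0:
        raise ValueError("no column reaches 50% occupancy; cannot build profile")

    counts = np.full((M, 20), pseudocount, dtype=float)
    bg = np.full(20, pseudocount, dtype=float)
    for r in rows:
        for a in r:
            if a in _AA_INDEX:
                bg[_AA_INDEX[a]] += 1
    for k, c in enumerate(match_cols):
        for r in rows:
            a = r[c]
            if a in _AA_INDEX:
                counts[k, _AA_INDEX[a]] += 1
    match_em = counts / counts.sum(axis=1, keepdims=True)
    background = bg / bg.sum()

    # transition counts between consecutive profile nodes
    tcounts = {k: np.full(max(M - 1, 0), pseudocount, dtype=float) for k in _TRANS}
    match_set = set(match_cols)
    for r in rows:
        for k in range(M - 1):
            c0, c1 = match_cols[k], match_cols[k + 1]
            s0 = "M" if r[c0] != "-" else "D"
            s1 = "M" if r[c1] != "-" else "D"
            n_ins = sum(1 for c in range(c0 + 1, c1) if c not in match_set and r[c] != "-")
            if n_ins > 0:
                # insert residues hang off node k; D..I adjacency collapses to M->I
                tcounts["MI"][k] += 1
                tcounts["II"][k] += n_ins - 1
                tcounts["IM"][k] += 1
            else:
                tcounts[s0 + s1][k] += 1
    transitions = {}
    if M > 1:
        for grp in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            tot = sum(tcounts[k] for k in grp)
            for k in grp:
                transitions[k] = tcounts[k] / tot
    else:
        transitions = {k: np.zeros(0) for k in _TRANS}
    return ProfileHMM(
        name=name,
        match_emissions=match_em,
        background=background,
        transitions=transitions,
    )


def _viterbi_matrices(profile: ProfileHMM, enc: np.ndarray):
    """Run the local Viterbi DP; returns (VM, VI, VD) with shape (L+1, M)."""
    M = profile.M
    L = len(enc)
    NEG = -1e30
    em = profile._em_bits
    t = profile._t_bits
    VM = np.full((L + 1, M), NEG)
    VI = np.full((L + 1, M), NEG)
    VD = np.full((L + 1, M), NEG)
    entry = profile._entry_bits
    if M > 1:
        sdd = np.concatenate(([0.0], np.cumsum(t["DD"])))  # sdd[j] = sum t_DD[0:j]
    for i in range(1, L + 1):
        erow = em[:, enc[i - 1]]
        best_prev = np.full(M, entry)
        if M > 1:
            cand = np.maximum(
                VM[i - 1, :-1] + t["MM"],
                np.maximum(VI[i - 1, :-1] + t["IM"], VD[i - 1, :-1] + t["DM"]),
            )
            best_prev[1:] = np.maximum(best_prev[1:], cand)
        VM[i] = erow + best_prev
        if M > 1:
            VI[i, :-1] = np.maximum(VM[i - 1, :-1] + t["MI"], VI[i - 1, :-1] + t["II"])
            # VD[i, j] = max over k <= j-1 of VM[i,k] + tMD[k] + sum tDD[k+1..j-1]
            a = VM[i, :-1] + t["MD"] - sdd[1:]
            VD[i, 1:] = np.maximum.accumulate(a) + sdd[1:]
    return VM, VI, VD


def viterbi_local(profile: ProfileHMM, seq: str, with_span: bool = False):
    """Best local alignment score of `seq` against the profile, in bits.

    Returns the score, or (score, (start, end)) 1-based when with_span is
    set. Residues outside the 20-letter alphabet score 0 bits (background).
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    enc = _encode(seq.upper())
    VM, VI, VD = _viterbi_matrices(profile, enc)
    flat = np.argmax(VM)
    i_end, j_end = divmod(int(flat), profile.M)
    score = float(VM[i_end, j_end])
    if not with_span:
        return score
    # traceback to the entry cell to recover the start position; at each M
    # cell the best predecessor is re-derived (entry preferred on ties so
    # the reported span is the shortest optimal one)
    t = profile._t_bits
    entry = profile._entry_bits
    i, j, state = i_end, j_end, "M"
    tol = 1e-7
    while True:
        if state == "M":
            if j == 0:
                break
            cands = [
                ("entry", entry),
                ("M", VM[i - 1, j - 1] + t["MM"][j - 1]),
                ("I", VI[i - 1, j - 1] + t["IM"][j - 1]),
                ("D", VD[i - 1, j - 1] + t["DM"][j - 1]),
            ]
            best_val = max(v for _, v in cands)
            pick = next(name for name, v in cands if v >= best_val - tol)
            if pick == "entry":
                break
            i, j, state = i - 1, j - 1, pick
        elif state == "I":
            if VM[i - 1, j] + t["MI"][j] >= VI[i - 1, j] + t["II"][j] - tol:
                state = "M"
            i = i - 1
        else:  # D: does not emit
            if VM[i, j - 1] + t["MD"][j - 1] >= VD[i, j - 1] + t["DD"][j - 1] - tol:
                state = "M"
            j = j - 1
    return score, (i, i_end)


def _viterbi_scores_batch(profile: ProfileHMM, seqs: np.ndarray) -> np.ndarray:
    """Scores for a batch of equal-length encoded sequences, shape (n, L)."""
    n, L = seqs.shape
    M = profile.M
    NEG = -1e30
    em = profile._em_bits
    t = profile._t_bits
    entry = profile._entry_bits
    prevM = np.full((n, M), NEG)
    prevI = np.full((n, M), NEG)
    prevD = np.full((n, M), NEG)
    best = np.full(n, NEG)
    if M > 1:
        sdd = np.concatenate(([0.0], np.cumsum(t["DD"])))
    for i in range(L):
        erow = em[:, seqs[:, i]].T  # (n, M)
        curM = np.full((n, M), entry)
        if M > 1:
            cand = np.maximum(
                prevM[:, :-1] + t["MM"],
                np.maximum(prevI[:, :-1] + t["IM"], prevD[:, :-1] + t["DM"]),
            )
            curM[:, 1:] = np.maximum(curM[:, 1:], cand)
        curM += erow
        curI = np.full((n, M), NEG)
        curD = np.full((n, M), NEG)
        if M > 1:
            curI[:, :-1] = np.maximum(prevM[:, :-1] + t["MI"], prevI[:, :-1] + t["II"])
            a = curM[:, :-1] + t["MD"] - sdd[1:]
            curD[:, 1:] = np.maximum.accumulate(a, axis=1) + sdd[1:]
        best = np.maximum(best, curM.max(axis=1))
        prevM, prevI, prevD = curM, curI, curD
    return best


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sd*sqrt(6)), mu = mean - gamma/lambda."""
    scores = np.asarray(scores, dtype=float)
    sd = float(scores.std(ddof=1))
    if sd == 0 or not math.isfinite(sd):
        raise CalibrationError("degenerate score distribution (zero variance)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - _EULER_GAMMA / lam
    return lam, mu


def calibrate(
    profile: ProfileHMM, n_random: int = 1000, random_len: int = 400, seed: int = 0
) -> tuple[float, float]:
    """Fit the Gumbel score null on random background peptides; store it."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a usable fit")
    rng = np.random.default_rng(seed)
    seqs = rng.choice(20, size=(n_random, random_len), p=profile.background)
    scores = _viterbi_scores_batch(profile, seqs)
    lam, mu = fit_gumbel(scores)
    profile.calibration = (lam, mu)
    return lam, mu


def gumbel_tail(score: float, lam: float, mu: float) -> float:
    """P(S >= score) under Gumbel(lambda, mu), numerically stable."""
    x = lam * (score - mu)
    if x > 700:
        return math.exp(-x)
    return -math.expm1(-math.exp(-x))


def scan(
    profiles: Iterable[ProfileHMM],
    seqs: Sequence[SeqRecord],
    evalue_threshold: float = 1e-5,
) -> list[DomainHit]:
    """Scan peptides against calibrated profiles; keep hits with E < threshold.

    E = n_seqs * P(S >= s) under the profile's Gumbel null. Hits are sorted
    by E-value ascending (ties by profile, seq id).
    """
    seqs = list(seqs)
    n = len(seqs)
    hits: list[DomainHit] = []
    for profile in profiles:
        if profile.calibration is None:
            raise RuntimeError(f"profile {profile.name!r} is not calibrated")
        lam, mu = profile.calibration
        for rec in seqs:
            score, (s, e) = viterbi_local(profile, rec.seq, with_span=True)
            ev = n * gumbel_tail(score, lam, mu)
            if ev < evalue_threshold:
                hits.append(
                    DomainHit(
                        profile_name=profile.name,
                        seq_id=rec.id,
                        seq_start=s,
                        seq_end=e,
                        bitscore=score,
                        evalue=ev,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, h.profile_name, h.seq_id))
    return hits


def save_profiles(profiles: Iterable[ProfileHMM], path: str | Path) -> None:
    """Serialize profiles to a plain-text format (one block per profile)."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f"PROFILE {p.name} M={p.M}\n")
            fh.write("BG " + " ".join(f"{x:.8g}" for x in p.background) + "\n")
            if p.calibration is not None:
                fh.write(f"CAL {p.calibration[0]:.8g} {p.calibration[1]:.8g}\n")
            for k in range(p.M):
                fh.write("ME " + " ".join(f"{x:.8g}" for x in p.match_emissions[k]) + "\n")
            for key in _TRANS:
                fh.write(f"T{key} " + " ".join(f"{x:.8g}" for x in p.transitions[key]) + "\n")
            fh.write("//\n")


def load_profiles(path: str | Path) -> list[ProfileHMM]:
    profiles: list[ProfileHMM] = []
    name = None
    bg = cal = None
    me: list[list[float]] = []
    trans: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("PROFILE "):
            name = line.split()[1]
            bg, cal, me, trans = None, None, [], {}
        elif line.startswith("BG "):
            bg = np.array([float(x) for x in line.split()[1:]])
        elif line.startswith("CAL "):
            cal = tuple(float(x) for x in line.split()[1:])
        elif line.startswith("ME "):
            me.append([float(x) for x in line.split()[1:]])
        elif line.startswith("T") and line[1:3] in _TRANS:
            trans[line[1:3]] = np.array([float(x) for x in line.split()[1:]])
        elif line == "//":
            p = ProfileHMM(
                name=name,
                match_emissions=np.array(me),
                background=bg,
                transitions=trans,
            )
            p.calibration = cal
            profiles.append(p)
    return profiles
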