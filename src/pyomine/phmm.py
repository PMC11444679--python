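"""Profile hidden Markov models built from seed alignments.

Match-state emissions are scored as log-odds (bits) against a background
distribution and state transitions contribute their log2 probabilities, so a
sequence close to the seed consensus accumulates a large positive bit score
while unrelated sequence scores at or below zero.  The model topology is the
usual match/insert/delete column layout; Viterbi scoring supports a global
mode (whole sequence against whole model) and a local mode in which flanking
sequence outside the best-scoring envelope is free.

These scores drive the receptor-domain gating (STN/Plug/TonB), the R1/R2
region scores that separate FpvA from FpvB and other TonB-dependent
receptors, and the NRPS domain scan used during cluster location.  Absolute
bit values depend on seed and background choices, so every gate threshold is
configuration, not a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pyomine.seqcore import AMINO_ACIDS, GAP, MultipleAlignment, ProteinSequence

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG = -1e30

#: transition source/target order used in the transition tensor
_FROM = ("M", "I", "D")
_TO = ("M", "D", "I")


@dataclass
class DomainHit:
    """Best-scoring placement of a model on a target sequence."""

    model: str
    target: str
    start: int  # 0-based half-open envelope on the target
    end: int
    score: float  # log-odds bits

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError("invalid envelope coordinates")
        if not math.isfinite(self.score):
            raise ValueError("hit score must be finite")


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with log-odds emission scoring.

    Attributes
    ----------
    match_emissions : (L, 20) probabilities per match state.
    transitions : (L+1, 3, 3) probabilities; ``transitions[j, f, t]`` is the
        probability of moving from state ``_FROM[f]`` at column j to
        ``_TO[t]`` (M/D advance to column j+1; I stays at column j).  Column 0
        is the begin state (no D0); column L transitions into the end state
        via the "M" target.
    background : (20,) residue frequencies used for log-odds.
    """

    name: str
    match_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        L = self.length
        if L < 1:
            raise ValueError("model needs at least one match state")
        if self.transitions.shape != (L + 1, 3, 3):
            raise ValueError("transition tensor shape mismatch")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")
        if not np.allclose(self.transitions.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(
            AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1)
        )

    # -- persistence --------------------------------------------------------

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"PYOHMM 1\nNAME {self.name}\nLENG {self.length}\n")
            fh.write("ALPH " + AMINO_ACIDS + "\n")
            fh.write("BG " + " ".join(f"{x:.8g}" for x in self.background) + "\n")
            for j in range(self.length):
                fh.write(
                    f"M{j + 1} "
                    + " ".join(f"{x:.8g}" for x in self.match_emissions[j])
                    + "\n"
                )
            for j in range(self.length + 1):
                fh.write(
                    f"T{j} "
                    + " ".join(f"{x:.8g}" for x in self.transitions[j].ravel())
                    + "\n"
                )

    @classmethod
    def from_text(cls, path) -> "ProfileHMM":
        name = ""
        length = 0
        background = None
        emissions = []
        transitions = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                tag = parts[0]
                if tag == "NAME":
                    name = parts[1]
                elif tag == "LENG":
                    length = int(parts[1])
                elif tag == "BG":
                    background = np.array([float(x) for x in parts[1:]])
                elif tag.startswith("M") and tag[1:].isdigit():
                    emissions.append([float(x) for x in parts[1:]])
                elif tag.startswith("T") and tag[1:].isdigit():
                    transitions.append(
                        np.array([float(x) for x in parts[1:]]).reshape(3, 3)
                    )
        if len(emissions) != length or len(transitions) != length + 1:
            raise ValueError("malformed model file")
        return cls(name, np.array(emissions), np.array(transitions), background)

    @classmethod
    def from_hmmer(cls, path, background: np.ndarray | None = None) -> "ProfileHMM":
        """Import the match-emission core of a HMMER3 .hmm file (optional)."""
        import pyhmmer

        with pyhmmer.plan7.HMMFile(str(path)) as hf:
            hmm = next(iter(hf))
        alphabet = hmm.alphabet.symbols[: hmm.alphabet.K]
        mat = np.asarray(hmm.match_emissions)[1:]  # row 0 is the dummy state
        cols = [alphabet.index(a) for a in AMINO_ACIDS]
        emis = mat[:, cols]
        emis = emis / emis.sum(axis=1, keepdims=True)
        L = emis.shape[0]
        trans = _default_transitions(L)
        bg = background if background is not None else np.full(20, 0.05)
        name = hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name)
        return cls(name, emis, trans, bg)


def _default_transitions(L: int, stay: float = 0.9) -> np.ndarray:
    t = np.zeros((L + 1, 3, 3))
    rest = (1 - stay) / 2
    t[:, :, 0] = stay
    t[:, :, 1] = rest
    t[:, :, 2] = rest
    return t


def build_phmm(
    seed: MultipleAlignment,
    name: str,
    max_gap_fraction: float = 0.5,
    emission_pseudocount: float = 1.0,
    transition_pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose gap fraction is below `max_gap_fraction` become match
    states; all others are treated as insert columns.  Emissions receive
    Laplace pseudocounts (+1 per residue by default) so that tiny seeds — the
    FpvB region seed has six rows — never produce zero probabilities, and
    transition counts receive +0.1.
    """
    if seed.n_rows < 2:
        raise ValueError("seed alignment needs at least two rows")
    ncol = seed.n_columns
    gap_frac = np.array(
        [seed.column(j).count(GAP) / seed.n_rows for j in range(ncol)]
    )
    match_cols = [j for j in range(ncol) if gap_frac[j] < max_gap_fraction]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no match columns under the gap-fraction rule")

    emis = np.full((L, 20), emission_pseudocount)
    for k, j in enumerate(match_cols):
        for c in seed.column(j):
            if c in _AA_INDEX:
                emis[k, _AA_INDEX[c]] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts along each row's state path
    tcounts = np.full((L + 1, 3, 3), transition_pseudocount)
    match_set = {j: k for k, j in enumerate(match_cols)}
    for row in seed.rows:
        state, col_idx = "M", 0  # begin state == M at column 0
        for j in range(ncol):
            ch = row.residues[j]
            if j in match_set:
                nxt = "M" if ch != GAP else "D"
                tcounts[col_idx, _FROM.index(state), _TO.index(nxt)] += 1.0
                state, col_idx = nxt, match_set[j] + 1
            elif ch != GAP:  # insert residue at the current column index
                tcounts[col_idx, _FROM.index(state), _TO.index("I")] += 1.0
                state = "I"
        tcounts[col_idx, _FROM.index(state), _TO.index("M")] += 1.0  # -> end
    trans = tcounts / tcounts.sum(axis=2, keepdims=True)

    bg = np.asarray(background, dtype=float) if background is not None else np.full(20, 0.05)
    return ProfileHMM(name, emis, trans, bg)


def _emission_scores(model: ProfileHMM, residues: str) -> np.ndarray:
    """(L, n) log2-odds of each match state emitting each residue ('X' -> 0)."""
    logodds = np.log2(model.match_emissions / model.background)
    n = len(residues)
    out = np.zeros((model.length, n))
    for i, ch in enumerate(residues):
        if ch in _AA_INDEX:
            out[:, i] = logodds[:, _AA_INDEX[ch]]
    return out


def score_sequence(
    model: ProfileHMM, s: ProteinSequence, mode: str = "local"
) -> DomainHit:
    """Viterbi log-odds score of a sequence against the model, in bits.

    Global mode consumes the entire sequence through the model (leading and
    trailing residues pass through insert states at a cost); local mode lets
    sequence outside the best envelope pass for free and reports the envelope.
    """
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    res = s.residues.replace(GAP, "")
    n = len(res)
    L = model.length
    emis = _emission_scores(model, res)
    with np.errstate(divide="ignore"):
        lt = np.log2(model.transitions)
    lt = np.maximum(lt, _NEG)

    M = np.full((L + 1, n + 1), _NEG)
    I = np.full((L + 1, n + 1), _NEG)
    D = np.full((L + 1, n + 1), _NEG)
    if mode == "global":
        M[0, 0] = 0.0
    else:
        M[0, :] = 0.0  # free N-flank

    iM, iI, iD = (_FROM.index(x) for x in _FROM)
    tM, tD, tI = (_TO.index(x) for x in _TO)

    def fill_insert(j: int) -> None:
        # I[j, i] = max(M[j, i-1] + t(M->I), I[j, i-1] + t(I->I), D[j, i-1] + t(D->I))
        # solved in closed form over the self-loop chain with a running max
        tMI = lt[j, iM, tI]
        tII = lt[j, iI, tI]
        tDI = lt[j, iD, tI]
        src = np.maximum(M[j] + tMI, D[j] + tDI)  # entry scores at position k
        k = np.arange(n + 1)
        g = src - k * tII
        run = np.maximum.accumulate(g)
        I[j, 1:] = run[:-1] + k[1:] * tII  # insert emissions score 0 (bg)

    fill_insert(0)
    for j in range(1, L + 1):
        prevM, prevI, prevD = M[j - 1], I[j - 1], D[j - 1]
        tj = lt[j - 1]
        # delete: advances the model, consumes nothing
        D[j] = np.max(
            np.stack(
                [prevM + tj[iM, tD], prevI + tj[iI, tD], prevD + tj[iD, tD]]
            ),
            axis=0,
        )
        best_prev = np.max(
            np.stack(
                [prevM + tj[iM, tM], prevI + tj[iI, tM], prevD + tj[iD, tM]]
            ),
            axis=0,
        )
        if j <= L:
            M[j, 1:] = emis[j - 1] + best_prev[:-1]
            M[j, 0] = _NEG
        fill_insert(j)

    tj = lt[L]
    end = np.max(
        np.stack([M[L] + tj[iM, tM], I[L] + tj[iI, tM], D[L] + tj[iD, tM]]),
        axis=0,
    )
    if mode == "global":
        score = float(end[n])
        return DomainHit(model.name, s.id, 0, n, max(score, -1e6))
    end_i = int(np.argmax(end))
    score = float(end[end_i])
    start_i = _trace_start(model, res, emis, lt, M, I, D, end_i)
    return DomainHit(model.name, s.id, start_i, end_i, max(score, -1e6))


def _trace_start(model, res, emis, lt, M, I, D, end_i: int) -> int:
    """Walk back through the stored Viterbi matrices to the envelope start."""
    iM, iI, iD = 0, 1, 2
    tM, tD, tI = 0, 1, 2
    L = model.length
    tj = lt[L]
    cands = (
        (M[L, end_i] + tj[iM, tM], "M"),
        (I[L, end_i] + tj[iI, tM], "I"),
        (D[L, end_i] + tj[iD, tM], "D"),
    )
    state = max(cands)[1]
    j, i = L, end_i
    tol = 1e-6
    guard = 0
    while j > 0 or state != "M":
        guard += 1
        if guard > 10 * (L + len(res) + 2):
            break
        if state == "M":
            target = M[j, i] - emis[j - 1, i - 1]
            tjm = lt[j - 1]
            opts = (
                (M[j - 1, i - 1] + tjm[iM, tM], "M"),
                (I[j - 1, i - 1] + tjm[iI, tM], "I"),
                (D[j - 1, i - 1] + tjm[iD, tM], "D"),
            )
            j, i = j - 1, i - 1
        elif state == "D":
            target = D[j, i]
            tjm = lt[j - 1]
            opts = (
                (M[j - 1, i] + tjm[iM, tD], "M"),
                (I[j - 1, i] + tjm[iI, tD], "I"),
                (D[j - 1, i] + tjm[iD, tD], "D"),
            )
            j = j - 1
        else:  # insert at column j
            target = I[j, i]
            tjc = lt[j]
            opts = (
                (M[j, i - 1] + tjc[iM, tI], "M"),
                (I[j, i - 1] + tjc[iI, tI], "I"),
                (D[j, i - 1] + tjc[iD, tI], "D"),
            )
            i = i - 1
        state = "M"
        for val, st in opts:
            if abs(val - target) < tol:
                state = st
                break
    return i


def scan_domains(
    s: ProteinSequence, models: list[ProfileHMM]
) -> list[DomainHit]:
    """Best local hit of each model on the target, sorted by envelope start."""
    hits = [score_sequence(m, s, mode="local") for m in models]
    return sorted(hits, key=lambda h: (h.start, h.end, h.model))
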