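"""Coiled-coil propensity scoring and nuclear-localization-signal decoding.

The coiled-coil scorer is a deliberately simple heptad-register propensity
profile: for every 21-residue window it tries all 7 register phases, rewards
hydrophobic residues at the core *a*/*d* positions and polar/charged ones at
*e*/*g*, and maps the best phase score through a logistic to [0, 1]. It is a
transparent stand-in for full coiled-coil HMMs (MARCOIL-style 9FAM models),
which are not reproduced here.

NLS detection uses a two-state (background/signal) hidden Markov model over
amino acids with exact Viterbi and posterior (forward-backward) decoding in
log space. The default parameterisation makes the signal state strongly
K/R-emitting, the classic basic-stretch NLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

from .core_io import SequenceRecord
from .motifs import AA20, AA_INDEX

CC_WINDOW = 21
CC_HYDROPHOBIC = set("LIVMF")  # favoured at heptad a/d
CC_POLAR = set("EKRQDN")       # favoured at heptad e/g
CC_LOGISTIC_SLOPE = 12.0
CC_LOGISTIC_MIDPOINT = 0.25


@dataclass(frozen=True)
class SignalCall:
    protein_id: str
    kind: str  # "CC" or "NLS"
    start: int  # 1-based inclusive
    end: int
    support: float  # max per-residue probability/posterior inside the segment


@dataclass
class TwoStateHMM:
    """Background/signal HMM over the 20-letter amino-acid alphabet.

    ``init`` and the rows of ``trans`` (2x2) and ``emit`` (2x20) are
    probability vectors; state 0 is background, state 1 is signal. Unknown
    residues (X) are emitted with probability 1 by both states, i.e. they
    carry no information.
    """

    init: np.ndarray
    trans: np.ndarray
    emit: np.ndarray

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.emit = np.asarray(self.emit, dtype=float)
        if self.init.shape != (2,) or self.trans.shape != (2, 2) or self.emit.shape != (2, 20):
            raise ValueError("expected init (2,), trans (2,2), emit (2,20)")
        for name, arr in (("init", self.init[None, :]), ("trans", self.trans),
                          ("emit", self.emit)):
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")

    @classmethod
    def default_nls(cls) -> "TwoStateHMM":
        """Static default: rare, persistent, strongly K/R-emitting signal state."""
        emit_sig = np.full(20, 0.24 / 18)
        emit_sig[AA_INDEX["K"]] = 0.38
        emit_sig[AA_INDEX["R"]] = 0.38
        return cls(
            init=np.array([0.95, 0.05]),
            trans=np.array([[0.995, 0.005], [0.10, 0.90]]),
            emit=np.vstack([np.full(20, 0.05), emit_sig]),
        )

    @classmethod
    def from_yaml(cls, path) -> "TwoStateHMM":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        emit = np.zeros((2, 20))
        for s, key in enumerate(("background", "signal")):
            for aa, p in d["emit"][key].items():
                emit[s, AA_INDEX[aa]] = p
        return cls(init=np.array(d["init"]), trans=np.array(d["trans"]), emit=emit)

    def log_emissions(self, residues: str) -> np.ndarray:
        """(L, 2) log emission probabilities; X rows are zero."""
        out = np.zeros((len(residues), 2))
        log_emit = np.log(self.emit)
        for i, aa in enumerate(residues):
            j = AA_INDEX.get(aa)
            if j is not None:
                out[i] = log_emit[:, j]
        return out


# ---------------------------------------------------------------------------
# Coiled-coil profile


def cc_probability_profile(seq: SequenceRecord) -> np.ndarray:
    """Per-residue coiled-coil probability in [0, 1], length = sequence length.

    Each 21-residue window is scored under its best of 7 heptad register
    phases (mean of +/-1 propensities at the a/d and e/g positions) and the
    score is assigned to the window centre; edge positions take the nearest
    window value. Sequences shorter than the window get an all-zero profile
    with a warning.
    """
    L = len(seq)
    if L < CC_WINDOW:
        warnings.warn(
            f"{seq.id}: length {L} is below the coiled-coil window {CC_WINDOW}",
            stacklevel=2,
        )
        return np.zeros(L)
    # per-residue, per-phase propensities: heptad index of residue i under
    # phase r is (i + r) % 7; positions 0/3 are a/d, 4/6 are e/g
    prop = np.zeros((7, L))
    for i, aa in enumerate(seq.residues):
        for r in range(7):
            h = (i + r) % 7
            if h in (0, 3):
                prop[r, i] = 1.0 if aa in CC_HYDROPHOBIC else -1.0
            elif h in (4, 6):
                prop[r, i] = 1.0 if aa in CC_POLAR else -1.0
    # mean over the 12 scored positions of each window, per phase
    kernel = np.ones(CC_WINDOW)
    n_scored = 12.0  # 4 scored positions per heptad x 3 heptads
    window_scores = np.vstack(
        [np.convolve(prop[r], kernel, mode="valid") / n_scored for r in range(7)]
    ).max(axis=0)
    probs = 1.0 / (1.0 + np.exp(-CC_LOGISTIC_SLOPE * (window_scores - CC_LOGISTIC_MIDPOINT)))
    profile = np.empty(L)
    half = CC_WINDOW // 2
    profile[half:half + len(probs)] = probs
    profile[:half] = probs[0]
    profile[half + len(probs):] = probs[-1]
    return profile


def call_cc(seq: SequenceRecord, threshold: float = 0.4) -> SignalCall | None:
    """The longest run of residues with CC probability >= threshold, or None.

    Ties between equally long runs go to the leftmost.
    """
    profile = cc_probability_profile(seq)
    above = profile >= threshold
    if not above.any():
        return None
    best = None  # (length, -start)
    i = 0
    L = len(above)
    while i < L:
        if above[i]:
            j = i
            while j + 1 < L and above[j + 1]:
                j += 1
            if best is None or (j - i + 1) > (best[1] - best[0] + 1):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    s, e = best
    return SignalCall(
        protein_id=seq.id, kind="CC", start=s + 1, end=e + 1,
        support=float(profile[s:e + 1].max()),
    )


# ---------------------------------------------------------------------------
# NLS decoding


def _forward(loge: np.ndarray, hmm: TwoStateHMM) -> np.ndarray:
    log_trans = np.log(hmm.trans)
    alpha = np.empty_like(loge)
    alpha[0] = np.log(hmm.init) + loge[0]
    for t in range(1, len(loge)):
        alpha[t] = loge[t] + logsumexp(alpha[t - 1][:, None] + log_trans, axis=0)
    return alpha


def _backward(loge: np.ndarray, hmm: TwoStateHMM) -> np.ndarray:
    log_trans = np.log(hmm.trans)
    beta = np.zeros_like(loge)
    for t in range(len(loge) - 2, -1, -1):
        beta[t] = logsumexp(log_trans + (loge[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def forward_loglik(seq: SequenceRecord, hmm: TwoStateHMM) -> float:
    loge = hmm.log_emissions(seq.residues)
    return float(logsumexp(_forward(loge, hmm)[-1]))


def backward_loglik(seq: SequenceRecord, hmm: TwoStateHMM) -> float:
    loge = hmm.log_emissions(seq.residues)
    beta = _backward(loge, hmm)
    return float(logsumexp(np.log(hmm.init) + loge[0] + beta[0]))


def posterior_signal(seq: SequenceRecord, hmm: TwoStateHMM) -> np.ndarray:
    """Per-residue posterior probability of the signal state."""
    loge = hmm.log_emissions(seq.residues)
    alpha = _forward(loge, hmm)
    beta = _backward(loge, hmm)
    log_post = alpha + beta
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post[:, 1])


def viterbi_path(seq: SequenceRecord, hmm: TwoStateHMM) -> np.ndarray:
    """Most probable state path (0 = background, 1 = signal)."""
    loge = hmm.log_emissions(seq.residues)
    log_trans = np.log(hmm.trans)
    L = len(loge)
    delta = np.empty((L, 2))
    back = np.zeros((L, 2), dtype=np.intp)
    delta[0] = np.log(hmm.init) + loge[0]
    for t in range(1, L):
        cand = delta[t - 1][:, None] + log_trans  # cand[i, j]
        back[t] = cand.argmax(axis=0)
        delta[t] = loge[t] + cand.max(axis=0)
    path = np.empty(L, dtype=np.intp)
    path[-1] = delta[-1].argmax()
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end) pairs."""
    runs = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def nls_decode(seq: SequenceRecord, hmm: TwoStateHMM | None = None,
               mode: str = "posterior", cutoff: float = 0.5) -> list[SignalCall]:
    """NLS segments by Viterbi or posterior decoding.

    Viterbi mode returns maximal runs of the signal state on the single most
    probable path; posterior mode returns maximal runs where the per-residue
    signal posterior is >= ``cutoff``. Support is the maximum signal
    posterior inside the segment in both modes.
    """
    if hmm is None:
        hmm = TwoStateHMM.default_nls()
    if mode not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decoding mode {mode!r}")
    post = posterior_signal(seq, hmm)
    if mode == "viterbi":
        mask = viterbi_path(seq, hmm) == 1
    else:
        mask = post >= cutoff
    return [
        SignalCall(protein_id=seq.id, kind="NLS", start=s + 1, end=e + 1,
                   support=float(post[s:e + 1].max()))
        for s, e in _runs(mask)
    ]
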