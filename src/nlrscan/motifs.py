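"""Conserved short-motif discovery and scanning for NLR domains.

Two routes exist to locate the NB-ARC-internal motifs (P-loop, Kinase-2,
RNBS-B, GLPL, MHDL):

* ``discover_zoops_motifs`` fits position probability matrices de novo by
  ZOOPS ("zero or one occurrence per sequence") expectation-maximisation,
  the model family popularised by MEME.
* ``scan_known_motifs`` scans a catalog of curated regex patterns or fitted
  :class:`MotifModel` matrices against single proteins.

``extract_signatures`` pulls the diagnostic residues out of Kinase-2
(the DDVW/DDVD dyad+2, which discriminates CC-lineage from TIR-lineage
receptors) and RNBS-B (TSR vs TTRD) hits.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .core_io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Curated default patterns, used when no fitted MotifModels are supplied.
#: ``signature`` is the sub-pattern whose match constitutes the signature
#: residues reported by :func:`extract_signatures`.
DEFAULT_PATTERNS: dict[str, dict] = {
    "P-loop": {"pattern": r"G[GAV].{2}G[KR][TS]T"},
    "Kinase-2": {"pattern": r"[LIVMF]{2}DD[VIML][WDR]", "signature": r"DD.."},
    "RNBS-B": {"pattern": r"[GN]S[RK][ILVMF]{3}T[TS]RD?", "signature": r"T[TS]RD?"},
    "GLPL": {"pattern": r"G[LIVM]PL[AG]"},
    "MHDL": {"pattern": r"[MQ]HD[LV]"},
}

#: Cap on total dataset residues accepted by the EM fitter.
MAXSIZE_RESIDUES = 100_000


@dataclass
class MotifModel:
    """A fixed-width position probability matrix with a ZOOPS occurrence prior."""

    name: str
    ppm: np.ndarray  # (width, 20), rows sum to 1, all cells > 0
    background: np.ndarray  # (20,)
    zoops_gamma: float = 0.5

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 20:
            raise ValueError("ppm must be (width, 20)")
        if np.any(self.ppm <= 0):
            raise ValueError("ppm cells must be strictly positive (pseudocounted)")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ppm rows must sum to 1")
        if not 0.0 <= self.zoops_gamma <= 1.0:
            raise ValueError("zoops_gamma must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.ppm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 21) log-odds; the extra column scores the unknown residue X as 0."""
        llr = np.log(self.ppm) - np.log(self.background)[None, :]
        return np.hstack([llr, np.zeros((self.width, 1))])


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_name: str
    start: int  # 1-based
    matched: str
    log_odds: float


@dataclass(frozen=True)
class SignatureResidues:
    kinase2: str | None = None
    rnbsb: str | None = None


def _encode(residues: str) -> np.ndarray:
    """Residues -> int codes; anything outside the 20-letter alphabet -> 20 (X)."""
    return np.array([AA_INDEX.get(a, 20) for a in residues], dtype=np.intp)


# ---------------------------------------------------------------------------
# ZOOPS EM


def _background_freqs(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.full(20, 1.0)  # +1 pseudocount keeps every frequency positive
    for enc in encoded:
        known = enc[enc < 20]
        counts += np.bincount(known, minlength=20)
    return counts / counts.sum()


def _window_scores(enc: np.ndarray, llr: np.ndarray) -> np.ndarray:
    """Log-odds of every width-w window of one sequence; shape (L - w + 1,)."""
    w = llr.shape[0]
    windows = sliding_window_view(enc, w)  # (P, w)
    return llr[np.arange(w)[None, :], windows].sum(axis=1)


_PAD = 21  # padding code; windows touching a pad position are invalid


def _batch(encoded: list[np.ndarray], width: int):
    """Pad usable sequences into (n, Lmax) int matrix plus window views."""
    usable = [e for e in encoded if len(e) >= width]
    lmax = max(len(e) for e in usable)
    mat = np.full((len(usable), lmax), _PAD, dtype=np.intp)
    for i, e in enumerate(usable):
        mat[i, :len(e)] = e
    windows = sliding_window_view(mat, width, axis=1)  # (n, P, w)
    n_pos = np.array([len(e) - width + 1 for e in usable])
    return usable, mat, windows, n_pos


def _em_iterate(ppm: np.ndarray, gamma: float, batch, background: np.ndarray,
                pseudocount: float, tol: float, max_iter: int):
    """EM iterations from a given state; returns (ppm, gamma, loglik, obj, trace)."""
    usable, mat, windows, n_pos = batch
    n, P, w = windows.shape
    valid = np.arange(P)[None, :] < n_pos[:, None]  # (n, P)
    cols = np.arange(w)
    log_bg = np.log(background)
    trace: list[float] = []
    loglik = objective = -np.inf
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: per-sequence posterior over start positions + absent state
        llr = np.hstack([np.log(ppm) - log_bg[None, :],
                         np.zeros((w, 1)),           # X: uninformative
                         np.full((w, 1), -1e30)])    # pad: invalid window
        scores = llr[cols[None, None, :], windows].sum(axis=-1)  # (n, P)
        scores = np.where(valid, scores, -1e30)
        log_present = np.log(max(gamma, 1e-300)) - np.log(n_pos)[:, None] + scores
        log_absent = np.full(n, np.log1p(-gamma) if gamma < 1.0 else -np.inf)
        total = logsumexp(np.hstack([log_absent[:, None], log_present]), axis=1)
        post = np.exp(log_present - total[:, None])  # (n, P)
        loglik = float(total.sum())

        # M-step (MAP with Dirichlet pseudocounts)
        weights = post.ravel()
        counts = np.empty((w, 20))
        for j in range(w):
            counts[j] = np.bincount(windows[:, :, j].ravel(), weights=weights,
                                    minlength=_PAD + 1)[:20]
        ppm = counts + pseudocount
        ppm /= ppm.sum(axis=1, keepdims=True)
        gamma = float(np.clip(post.sum() / n, 1e-6, 1.0 - 1e-6))

        objective = loglik + pseudocount * np.log(ppm).sum()
        trace.append(objective)
        if prev > -np.inf and objective - prev < tol * abs(prev):
            break
        prev = objective
    return ppm, gamma, loglik, objective, trace


def _em_single(encoded: list[np.ndarray], width: int, background: np.ndarray,
               rng: np.random.Generator, pseudocount: float, tol: float,
               max_iter: int) -> tuple[np.ndarray, float, float, list[float]]:
    """One EM run at a fixed width from a random subsequence seed.

    After convergence the alignment phase is refined by trying +/-1 column
    shifts of the matrix (vacated columns refilled with background) and
    keeping a shift whenever re-converged EM improves the objective; plain
    ZOOPS EM cannot slide an established alignment, so partially
    overlapping seeds would otherwise stall one or two columns off.

    Returns (ppm, gamma, data log likelihood relative to background,
    objective trace). The traced objective adds the Dirichlet pseudocount
    term, which MAP-EM (and improvement-gated shifts) make non-decreasing.
    """
    batch = _batch(encoded, width)
    usable = batch[0]
    # seed the PPM from a random window: seed letter mass 0.5, rest background
    s = usable[rng.integers(len(usable))]
    pos = rng.integers(len(s) - width + 1)
    ppm = np.tile(background * 0.5, (width, 1))
    for j, letter in enumerate(s[pos:pos + width]):
        if letter < 20:
            ppm[j, letter] += 0.5
        else:
            ppm[j] += background * 0.5
    ppm /= ppm.sum(axis=1, keepdims=True)

    ppm, gamma, loglik, objective, trace = _em_iterate(
        ppm, 0.5, batch, background, pseudocount, tol, max_iter)
    for _ in range(2 * width):
        improved = False
        for delta in (1, -1):
            if delta == 1:   # window slides right
                cand = np.vstack([ppm[1:], background[None, :]])
            else:            # window slides left
                cand = np.vstack([background[None, :], ppm[:-1]])
            p2, g2, ll2, obj2, _ = _em_iterate(
                cand, gamma, batch, background, pseudocount, tol, max_iter=10)
            if obj2 > objective + 1e-9:
                ppm, gamma, loglik, objective = p2, g2, ll2, obj2
                trace.append(obj2)
                improved = True
                break
        if not improved:
            break
    return ppm, gamma, loglik, trace


def discover_zoops_motifs(
    seqs: list[SequenceRecord],
    nmotifs: int = 20,
    minw: int = 6,
    maxw: int = 25,
    seed: int = 0,
    n_restarts: int = 10,
    pseudocount: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
    width_penalty: float = 0.5,
    fixed_gamma: float | None = None,
) -> list[MotifModel]:
    """Discover up to ``nmotifs`` ZOOPS motifs by seeded EM with masking.

    Each motif is fitted independently at every width in [minw, maxw] with
    ``n_restarts`` random subsequence seeds; the winning width maximises the
    relative log likelihood minus ``width_penalty`` nats per column per
    sequence (a plain description-length penalty, since likelihoods at
    different widths are not directly comparable). The best occurrence of
    each accepted motif is masked before the next round. Setting
    ``fixed_gamma=1.0`` pins the occurrence prior and degenerates ZOOPS to
    OOPS (one occurrence per sequence).

    Discovery stops early when no width clears the penalty.
    """
    if len(seqs) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    total = sum(len(s) for s in seqs)
    if total > MAXSIZE_RESIDUES:
        raise ValueError(
            f"dataset has {total} residues, above the maxsize cap of "
            f"{MAXSIZE_RESIDUES}; subsample the input"
        )
    if not any(len(s) > minw for s in seqs):
        raise ValueError(f"all sequences are shorter than minw={minw}")

    rng = np.random.default_rng(seed)
    encoded = [_encode(s.residues) for s in seqs]
    background = _background_freqs(encoded)

    models: list[MotifModel] = []
    for m in range(nmotifs):
        best = None  # (penalised score, ppm, gamma)
        for width in range(minw, maxw + 1):
            if not any(len(e) >= width for e in encoded):
                continue
            for _ in range(n_restarts):
                ppm, gamma, obj, _tr = _em_single(
                    encoded, width, background, rng, pseudocount, tol, max_iter
                )
                if fixed_gamma is not None:
                    gamma = fixed_gamma
                score = obj - width_penalty * width * len(encoded)
                if best is None or score > best[0]:
                    best = (score, ppm, gamma)
        if best is None or best[0] <= 0.0:
            break
        _, ppm, gamma = best
        model = MotifModel(
            name=f"motif_{m + 1}", ppm=ppm, background=background, zoops_gamma=gamma
        )
        _mask_best_occurrences(encoded, model)
        models.append(model)
    return models


def zoops_objective_trace(seqs: list[SequenceRecord], width: int, seed: int = 0,
                          pseudocount: float = 0.1, tol: float = 1e-6,
                          max_iter: int = 200) -> list[float]:
    """Objective values of a single EM run at a fixed width (for diagnostics)."""
    rng = np.random.default_rng(seed)
    encoded = [_encode(s.residues) for s in seqs]
    background = _background_freqs(encoded)
    *_, trace = _em_single(encoded, width, background, rng, pseudocount, tol, max_iter)
    return trace


def _mask_best_occurrences(encoded: list[np.ndarray], model: MotifModel) -> None:
    """Overwrite each sequence's best occurrence (when present) with X codes."""
    llr = model.log_odds()
    w = model.width
    for enc in encoded:
        if len(enc) < w:
            continue
        scores = _window_scores(enc, llr)
        P = len(scores)
        g = model.zoops_gamma
        log_present = np.log(max(g, 1e-300)) - np.log(P) + scores
        log_absent = np.log1p(-g) if g < 1.0 else -np.inf
        if logsumexp(log_present) > log_absent:
            j = int(scores.argmax())
            enc[j:j + w] = 20


def best_occurrence(seq: SequenceRecord, model: MotifModel) -> MotifHit | None:
    """Highest-scoring window of ``model`` in ``seq``, or None if too short."""
    enc = _encode(seq.residues)
    if len(enc) < model.width:
        return None
    scores = _window_scores(enc, model.log_odds())
    j = int(scores.argmax())
    return MotifHit(
        protein_id=seq.id,
        motif_name=model.name,
        start=j + 1,
        matched=seq.residues[j:j + model.width],
        log_odds=float(scores[j]),
    )


# ---------------------------------------------------------------------------
# Catalog scanning


def _pattern_occurrences(seq: SequenceRecord, name: str, pattern: str) -> list[MotifHit]:
    hits = []
    rx = re.compile(f"(?=({pattern}))")
    for m in rx.finditer(seq.residues):
        matched = m.group(1)
        hits.append(
            MotifHit(
                protein_id=seq.id,
                motif_name=name,
                start=m.start() + 1,
                matched=matched,
                log_odds=float(len(matched)),
            )
        )
    return hits


def _model_occurrences(seq: SequenceRecord, model: MotifModel,
                       threshold: float) -> list[MotifHit]:
    enc = _encode(seq.residues)
    if len(enc) < model.width:
        return []
    scores = _window_scores(enc, model.log_odds())
    return [
        MotifHit(
            protein_id=seq.id,
            motif_name=model.name,
            start=j + 1,
            matched=seq.residues[j:j + model.width],
            log_odds=float(scores[j]),
        )
        for j in np.flatnonzero(scores > threshold)
    ]


def resolve_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlap selection: descending log-odds, ties by leftmost start."""
    chosen: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.log_odds, h.start)):
        span = range(h.start, h.start + len(h.matched))
        if all(
            span.stop <= c.start or span.start >= c.start + len(c.matched)
            for c in chosen
        ):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)


def scan_known_motifs(
    seq: SequenceRecord,
    catalog: dict[str, dict] | list[MotifModel] | None = None,
    threshold: float = 0.0,
) -> list[MotifHit]:
    """All non-overlapping occurrences per motif, above threshold, sorted by start.

    ``catalog`` is either a name->{pattern, signature?} mapping of regex
    patterns (defaults to :data:`DEFAULT_PATTERNS`) or a list of fitted
    MotifModels scored by log-odds. Overlap resolution is applied within each
    motif; distinct motifs may overlap.
    """
    if catalog is None:
        catalog = DEFAULT_PATTERNS
    out: list[MotifHit] = []
    if isinstance(catalog, dict):
        for name, entry in catalog.items():
            out.extend(resolve_overlaps(_pattern_occurrences(seq, name, entry["pattern"])))
    else:
        for model in catalog:
            out.extend(resolve_overlaps(_model_occurrences(seq, model, threshold)))
    return sorted(out, key=lambda h: (h.start, h.motif_name))


# ---------------------------------------------------------------------------
# Signature residues


def extract_signatures(seq: SequenceRecord, hits: list[MotifHit],
                       catalog: dict[str, dict] | None = None) -> SignatureResidues:
    """Diagnostic residues from Kinase-2 and RNBS-B hits.

    kinase2 = the 4 residues starting at the first D of the DD dyad inside
    the Kinase-2 hit (extended into the protein when the match ends early);
    rnbsb = the match of the catalogued signature sub-pattern inside the
    RNBS-B hit. Fields are None when the corresponding hit is missing.
    """
    if catalog is None:
        catalog = DEFAULT_PATTERNS
    kinase2 = rnbsb = None
    for h in sorted(hits, key=lambda h: h.start):
        if h.motif_name == "Kinase-2" and kinase2 is None:
            dd = h.matched.find("DD")
            if dd < 0:
                warnings.warn(
                    f"{seq.id}: Kinase-2 hit {h.matched!r} has no DD dyad",
                    stacklevel=2,
                )
                continue
            abs_start = h.start - 1 + dd  # 0-based into the protein
            frag = seq.residues[abs_start:abs_start + 4]
            if len(frag) == 4:
                kinase2 = frag
        elif h.motif_name == "RNBS-B" and rnbsb is None:
            sig = catalog.get("RNBS-B", {}).get("signature")
            if sig:
                m = re.search(sig, h.matched)
                if m:
                    rnbsb = m.group(0)
    return SignatureResidues(kinase2=kinase2, rnbsb=rnbsb)
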