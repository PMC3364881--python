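"""Per-block profile HMMs: construction, scoring, Gumbel calibration, I/O.

A profile is estimated from a small ungapped-ish sub-alignment (a conserved
block). Columns with gap fraction < 0.5 become match states; the rest feed
insert states. Emissions and transitions are maximum-likelihood estimates
with background-proportional pseudocounts of total weight ``alpha``.

Scoring is local (uniform entry over match states, free exit) and returns
log-odds bit scores against the background null. Significance rests on the
classical extreme-value law for local alignment: optimal (Viterbi) local
scores of a probabilistic local model on random sequences follow a Gumbel
whose slope is ln 2 per bit, and calibration recovers (mu, lambda)
empirically from scored random background sequences:

    P(S > s) = 1 - exp(-exp(-lambda * (s - mu)))
    E(s)     = db_size * P(S > s)

where ``db_size`` is the number of translated segments scanned in a search.
The fitted lambda landing on ~0.69/bit is a built-in sanity check that the
calibration is in the theoretical regime.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import _dp
from .alphabet import (AA_LETTERS, N_AA, STOP_CODE, X_CODE, encode_protein,
                       robinson_background)
from .errors import BuildError, CalibrationError, FormatError, UncalibratedError, ValidationError

_TOL = 1e-9
# transition group layout: (M->M, M->I, M->D), (I->M, I->I), (D->M, D->D)
_T_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ScoredMatch:
    """One local alignment of a profile on an amino-acid sequence."""
    score: float                      # bits
    start: int                        # query interval [start, end)
    end: int
    path: Optional[list] = None


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray        # (L, 20) probability rows
    insert_emissions: np.ndarray       # (20,) shared background-style
    transitions: dict                  # name -> (L,) probability arrays
    background: np.ndarray             # (20,)
    calibration: Optional[tuple[float, float]] = None  # Gumbel (mu, lambda)
    _lod_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.L
        if L < 1:
            raise ValidationError("profile must have at least one match state")
        if self.match_emissions.shape != (L, N_AA):
            raise ValidationError("match emission shape mismatch")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=_TOL):
            raise ValidationError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=_TOL):
            raise ValidationError("insert emissions must sum to 1")
        t = self.transitions
        for name in _T_NAMES:
            if t[name].shape != (L,):
                raise ValidationError(f"transition '{name}' length mismatch")
        if L > 1:
            inner = slice(0, L - 1)
            for group in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
                s = sum(t[g][inner] for g in group)
                if not np.allclose(s, 1.0, atol=_TOL):
                    raise ValidationError(
                        f"transition group {group} must sum to 1 at every "
                        "internal position")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValidationError("calibration lambda must be positive")

    # --- scoring ----------------------------------------------------------

    def _lod(self):
        """Cached log-odds tables for the DP kernels (bits)."""
        if self._lod_cache is None:
            L = self.L
            with np.errstate(divide="ignore"):
                mlod = np.full((L, 22), _dp.NEG)
                mlod[:, :N_AA] = np.log2(self.match_emissions /
                                         self.background[None, :])
                mlod[:, X_CODE] = 0.0
                ilod = np.full(22, _dp.NEG)
                ilod[:N_AA] = np.log2(self.insert_emissions / self.background)
                ilod[X_CODE] = 0.0

                def tl(name):
                    return np.log2(self.transitions[name])
                tabs = (np.nan_to_num(mlod, neginf=_dp.NEG),
                        np.nan_to_num(ilod, neginf=_dp.NEG),
                        tuple(np.maximum(tl(n), _dp.NEG) for n in _T_NAMES))
            object.__setattr__(self, "_lod_cache", tabs)
        return self._lod_cache

    def score_segments(self, seq_codes: np.ndarray, offsets: np.ndarray,
                       algorithm: str = "viterbi"):
        """Score many stop-free segments at once; returns (scores, starts, ends)."""
        mlod, ilod, trans = self._lod()
        n = offsets.shape[0] - 1
        scores = np.empty(n)
        entry = -np.log2(self.L)
        if algorithm == "viterbi":
            starts = np.empty(n, dtype=np.int64)
            ends = np.empty(n, dtype=np.int64)
            _dp.viterbi_segments(seq_codes, offsets, mlod, ilod, *trans,
                                 entry, scores, starts, ends)
            return scores, starts, ends
        elif algorithm == "forward":
            _dp.forward_segments(seq_codes, offsets, mlod, ilod, *trans,
                                 entry, scores)
            return scores, None, None
        raise ValueError(f"unknown algorithm {algorithm!r}")


def _encode_checked(seq: str) -> np.ndarray:
    codes = encode_protein(seq)
    if (codes == STOP_CODE).any():
        raise ValidationError("'*' is never scored; split segments at stops")
    return codes


def viterbi(hmm: ProfileHMM, seq: str) -> ScoredMatch:
    """Best local alignment of ``hmm`` on ``seq`` (bit score + interval)."""
    if len(seq) == 0:
        return ScoredMatch(score=float("-inf"), start=0, end=0)
    codes = _encode_checked(seq)
    offsets = np.array([0, len(codes)], dtype=np.int64)
    scores, starts, ends = hmm.score_segments(codes, offsets, "viterbi")
    return ScoredMatch(score=float(scores[0]), start=int(starts[0]),
                       end=int(ends[0]))


def forward(hmm: ProfileHMM, seq: str) -> float:
    """Forward (all-paths) local bit score; always >= the Viterbi score."""
    if len(seq) == 0:
        return float("-inf")
    codes = _encode_checked(seq)
    offsets = np.array([0, len(codes)], dtype=np.int64)
    scores, _, _ = hmm.score_segments(codes, offsets, "forward")
    return float(scores[0])


# --- construction ---------------------------------------------------------

def profile_from_rows(rows: Sequence[str], alpha: float = 1.0,
                      background: Optional[np.ndarray] = None,
                      name: str = "block") -> ProfileHMM:
    """Estimate a profile from aligned rows (strings over residues + '-').

    Columns with gap fraction < 0.5 are match states. Emissions use
    background-proportional pseudocounts: (count + alpha*bg) / (n + alpha).
    Transitions are counted from per-sequence state paths with a uniform
    pseudocount of the same total weight alpha.
    """
    if background is None:
        background = robinson_background()
    if not rows:
        raise BuildError("empty block sub-alignment")
    if alpha < 0:
        raise ValidationError("pseudocount weight must be >= 0")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError("ragged block alignment")
    mat = np.array([[c for c in r.upper()] for r in rows])
    is_gap = (mat == "-") | (mat == ".")
    gap_frac = is_gap.mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < 0.5)
    if match_cols.size == 0:
        raise BuildError("all columns gapped; no match states")
    L = match_cols.size

    # emissions
    match_em = np.zeros((L, N_AA))
    for k, col in enumerate(match_cols):
        counts = np.zeros(N_AA)
        for r in range(len(rows)):
            c = mat[r, col]
            if not is_gap[r, col]:
                try:
                    counts[AA_LETTERS.index(c)] += 1.0
                except ValueError:
                    counts += background  # X etc: spread over background
        n = counts.sum()
        match_em[k] = (counts + alpha * background) / (n + alpha)

    # state paths -> transition counts
    col_role = np.full(ncol, -1)       # match index, or -1 for insert column
    for k, col in enumerate(match_cols):
        col_role[col] = k
    tc = {name: np.zeros(L) for name in _T_NAMES}
    totals = {"m": np.zeros(L), "i": np.zeros(L), "d": np.zeros(L)}
    for r in range(len(rows)):
        states = []                    # (kind, position)
        for col in range(ncol):
            k = col_role[col]
            if k >= 0:
                states.append(("d" if is_gap[r, col] else "m", k))
            elif not is_gap[r, col]:
                # insert after the last match position seen
                states.append(("i", states[-1][1] if states else -1))
        # drop flanking inserts outside the first/last match position (local)
        while states and states[0][0] == "i":
            states.pop(0)
        for (k1, p1), (k2, p2) in zip(states, states[1:]):
            totals[k1][p1] += 1.0
            tc[k1 + k2][p1] += 1.0
    transitions = {}
    for src, names in (("m", ("mm", "mi", "md")), ("i", ("im", "ii")),
                       ("d", ("dm", "dd"))):
        k = len(names)
        denom = totals[src] + alpha
        seen = denom > 0
        for nm in names:
            with np.errstate(invalid="ignore"):
                transitions[nm] = np.where(seen,
                                           (tc[nm] + alpha / k) / denom, 0.0)
        # states never visited with alpha = 0: return deterministically to
        # the match track (they are unreachable anyway)
        transitions[names[0]][~seen] = 1.0
    # position L-1 has no outgoing internal transition; zero it so the DP
    # never extends past the last match state
    if L >= 1:
        for nm in _T_NAMES:
            transitions[nm][L - 1] = 0.0

    hmm = ProfileHMM(name=name, match_emissions=match_em,
                     insert_emissions=background.copy(),
                     transitions=transitions, background=background.copy())
    hmm.validate()
    return hmm


def build_profile(block, alpha: float = 1.0,
                  background: Optional[np.ndarray] = None) -> ProfileHMM:
    """Build a ProfileHMM from a BlockDefinition (or raw aligned rows)."""
    if hasattr(block, "sub_alignment"):
        rows = [s for _, s in block.sub_alignment.sequences]
        name = f"block{block.index}"
    else:
        rows = list(block)
        name = "block"
    return profile_from_rows(rows, alpha=alpha, background=background,
                             name=name)


# --- calibration ----------------------------------------------------------

def sample_background(background: np.ndarray, n: int, length: int,
                      rng: np.random.Generator) -> np.ndarray:
    """(n, length) uint8 residue codes drawn i.i.d. from the background."""
    return rng.choice(N_AA, size=(n, length), p=background).astype(np.uint8)


def _fit_gumbel_mindist(scores: np.ndarray) -> tuple[float, float]:
    """Gumbel (location, scale) by minimum Cramér-von Mises distance.

    E-values are a statement about the null CDF, so the fit minimizes CDF
    misfit directly rather than density likelihood (under mild model
    misspecification ML systematically distorts the CDF). Deterministic:
    Nelder-Mead started from the ML estimate.
    """
    loc0, scale0 = stats.gumbel_r.fit(scores)
    emp = np.sort(scores)
    n = emp.shape[0]
    ecdf = (np.arange(1, n + 1) - 0.5) / n

    def obj(p):
        loc, scale = p
        if scale <= 0:
            return 1.0
        return float(np.mean((ecdf - stats.gumbel_r.cdf(emp, loc, scale))
                             ** 2))

    res = optimize.minimize(obj, [loc0, scale0], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-12})
    loc, scale = res.x
    if scale <= 0:
        loc, scale = loc0, scale0
    return float(loc), float(scale)


def calibrate(hmm: ProfileHMM, n_samples: int = 1000, sample_len: int = 100,
              seed: int = 0) -> ProfileHMM:
    """Fit a Gumbel null to Viterbi scores of random background sequences.

    Scores of 100-residue backgrounds are maxima over enough local-alignment
    "islands" that the extreme-value law holds across the distribution (and
    its ln 2 tail slope makes genome-scale E-values safe to extrapolate);
    shorter scanned segments then receive slightly conservative E-values.
    Returns a copy of ``hmm``; fully determined by the seed.
    """
    if n_samples < 100:
        raise ValidationError("calibration needs n_samples >= 100")
    rng = np.random.default_rng(seed)
    sample = sample_background(hmm.background, n_samples, sample_len, rng)
    seq = sample.ravel()
    offsets = np.arange(0, (n_samples + 1) * sample_len, sample_len,
                        dtype=np.int64)
    scores, _, _ = hmm.score_segments(seq, offsets, "viterbi")
    if np.std(scores) < 1e-12:
        raise CalibrationError("degenerate null score distribution")
    loc, scale = _fit_gumbel_mindist(scores)
    out = replace(hmm, calibration=(loc, 1.0 / scale))
    object.__setattr__(out, "_lod_cache", hmm._lod_cache)
    return out


def evalue(score: float, hmm: ProfileHMM, db_size: int) -> float:
    """Expected random hits >= ``score`` in a search of ``db_size`` segments."""
    if hmm.calibration is None:
        raise UncalibratedError(f"profile '{hmm.name}' is not calibrated")
    if db_size < 1:
        raise ValidationError("db_size must be >= 1")
    mu, lam = hmm.calibration
    return float(db_size * -np.expm1(-np.exp(-lam * (score - mu))))


def evalues_array(scores: np.ndarray, hmm: ProfileHMM,
                  db_size: int) -> np.ndarray:
    if hmm.calibration is None:
        raise UncalibratedError(f"profile '{hmm.name}' is not calibrated")
    mu, lam = hmm.calibration
    with np.errstate(over="ignore"):
        return db_size * -np.expm1(-np.exp(-lam * (scores - mu)))


# --- plain-text serialization --------------------------------------------

def write_profile(hmm: ProfileHMM, path) -> None:
    """Serialize a profile to the package's plain-text format."""
    lines = [f"PHMM\t1", f"NAME\t{hmm.name}", f"L\t{hmm.L}",
             f"ALPH\t{AA_LETTERS}",
             "BG\t" + "\t".join(f"{v:.17g}" for v in hmm.background),
             "INS\t" + "\t".join(f"{v:.17g}" for v in hmm.insert_emissions)]
    if hmm.calibration is not None:
        mu, lam = hmm.calibration
        lines.append(f"CAL\t{mu:.17g}\t{lam:.17g}")
    for j in range(hmm.L):
        lines.append(f"MATCH\t{j}\t" +
                     "\t".join(f"{v:.17g}" for v in hmm.match_emissions[j]))
    for j in range(hmm.L):
        lines.append(f"TRANS\t{j}\t" + "\t".join(
            f"{hmm.transitions[nm][j]:.17g}" for nm in _T_NAMES))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> ProfileHMM:
    text = Path(path).read_text().splitlines()
    fields = {}
    match_rows = {}
    trans_rows = {}
    for line in text:
        if not line.strip():
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "MATCH":
            match_rows[int(parts[1])] = [float(v) for v in parts[2:]]
        elif key == "TRANS":
            trans_rows[int(parts[1])] = [float(v) for v in parts[2:]]
        else:
            fields[key] = parts[1:]
    if "PHMM" not in fields or "L" not in fields:
        raise FormatError(f"{path}: not a profile file")
    L = int(fields["L"][0])
    if sorted(match_rows) != list(range(L)) or sorted(trans_rows) != list(range(L)):
        raise FormatError(f"{path}: missing emission/transition rows")
    transitions = {nm: np.array([trans_rows[j][i] for j in range(L)])
                   for i, nm in enumerate(_T_NAMES)}
    cal = None
    if "CAL" in fields:
        cal = (float(fields["CAL"][0]), float(fields["CAL"][1]))
    hmm = ProfileHMM(
        name=fields.get("NAME", ["block"])[0],
        match_emissions=np.array([match_rows[j] for j in range(L)]),
        insert_emissions=np.array([float(v) for v in fields["INS"]]),
        transitions=transitions,
        background=np.array([float(v) for v in fields["BG"]]),
        calibration=cal)
    hmm.validate()
    return hmm
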