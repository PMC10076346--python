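"""Peak-summit metaprofiles of folding free energy and GC content.

Each binding peak contributes a 500-nt window centered on its summit
(offsets -250..+249, strand-oriented).  For every position in the window the
151-nt subsequence spanning 75 nt up- and downstream is scored for GC
fraction and predicted folding free energy, and scores are averaged over
windows per offset.

Two folding backends exist: ``builtin`` is a simplified nested-structure
dynamic program (pair energies GC = -3, AU = -2, GU = -1 kcal/mol, minimum
hairpin loop 3 nt, no pseudoknots) so the profile shape is computable with no
external engine; ``external`` shells out to the RNAfold binary for
thermodynamic minimum free energies.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_junctions import Peak

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

# base encoding: A=0, C=1, G=2, U/T=3, N=4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _v in zip("ACGTU", (0, 1, 2, 3, 3)):
    _ENCODE[ord(_b)] = _v
    _ENCODE[ord(_b.lower())] = _v

MIN_LOOP = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return arr


@njit(cache=False)
def _pair_energy(a: np.int8, b: np.int8) -> float:
    # GC=-3, AU=-2, GU=-1; anything with N never pairs
    if (a == 2 and b == 1) or (a == 1 and b == 2):
        return -3.0
    if (a == 0 and b == 3) or (a == 3 and b == 0):
        return -2.0
    if (a == 2 and b == 3) or (a == 3 and b == 2):
        return -1.0
    return 0.0


@njit(cache=False)
def _nussinov_min_energy(enc: np.ndarray) -> float:
    n = enc.shape[0]
    if n < MIN_LOOP + 2:
        return 0.0
    E = np.zeros((n, n))
    for d in range(MIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            e = _pair_energy(enc[i], enc[j])
            if e < 0.0:
                v = e + (E[i + 1, j - 1] if j - 1 >= i + 1 else 0.0)
                if v < best:
                    best = v
            for k in range(i + 1, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return E[0, n - 1]


def _rnafold_mfe(seqs: Sequence[str]) -> list[float]:
    """Minimum free energies from the RNAfold binary (one batch call)."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold binary not found on PATH")
    inp = "".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs))
    proc = subprocess.run(
        [exe, "--noPS"], input=inp, capture_output=True, text=True, check=True
    )
    out: list[float] = []
    for line in proc.stdout.splitlines():
        line = line.strip()
        if line.endswith(")") and "(" in line:
            out.append(float(line[line.rindex("(") + 1 : -1]))
    if len(out) != len(seqs):
        raise RuntimeError("unexpected RNAfold output")
    return out


def fold_dG(seq: str, backend: str = "builtin") -> float:
    """Predicted folding free energy (<= 0, kcal/mol) of a sequence.

    ``builtin`` computes the optimal nested structure under the simplified
    pair-energy model; ``external`` uses the thermodynamic folding engine.
    Structureless sequences return 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    if any(c.upper() not in "ACGTUN" for c in seq):
        raise ValueError(f"invalid characters in sequence: {seq[:20]!r}...")
    if backend == "builtin":
        return float(_nussinov_min_energy(_encode(seq)))
    if backend == "external":
        return min(0.0, _rnafold_mfe([seq])[0])
    raise ValueError(f"unknown backend {backend!r}")


def gc_content(seq: str) -> float:
    """GC fraction; N bases are excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    gc = sum(c in "GC" for c in up)
    acgt = sum(c in "ACGTU" for c in up)
    if acgt == 0:
        return float("nan")
    return gc / acgt


# ---------------------------------------------------------------------------
# Peak merging and summit windows


def merge_longest(peaks: Sequence[Peak]) -> list[Peak]:
    """Within each connected overlap component keep only the longest peak.

    Ties break on the lowest start coordinate.  Intended for a single
    replicate's peak set.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[Peak] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        component: list[Peak] = []
        comp_end = -1
        for p in ps:
            if component and p.start >= comp_end:
                out.append(max(component, key=lambda q: (len(q), -q.start)))
                component = []
                comp_end = -1
            component.append(p)
            comp_end = max(comp_end, p.end)
        if component:
            out.append(max(component, key=lambda q: (len(q), -q.start)))
    return out


@dataclass(frozen=True)
class SummitWindow:
    """A 500-nt strand-oriented sequence window centered on a peak summit.

    ``ext_sequence`` additionally carries ``flank`` nt on each side so every
    position's 151-nt context can be sliced without further genome access;
    ``sequence`` is the central 500 nt.  Offset 0 is the summit (index
    ``half`` of the 500-nt window).
    """

    chrom: str
    summit: int
    strand: str
    ext_sequence: str
    half: int = 250
    flank: int = 75

    @property
    def sequence(self) -> str:
        return self.ext_sequence[self.flank : self.flank + 2 * self.half]

    @property
    def offsets(self) -> range:
        return range(-self.half, self.half)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Forward-strand sequence from a dict-of-strings or pyfaidx-like store."""
    if isinstance(genome, Mapping):
        ref = genome[chrom]
        seq = ref[start:end] if isinstance(ref, str) else "".join(ref[start:end])
        return seq.upper()
    return str(genome[chrom][start:end]).upper()  # pyfaidx.Fasta


def _chrom_len(genome, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    return len(genome[chrom])


def build_summit_windows(
    peaks: Sequence[Peak],
    genome,
    strands: str | Sequence[str] = "+",
    half: int = 250,
    flank: int = 75,
) -> list[SummitWindow]:
    """Summit-centered windows for a (merged) peak set.

    ``strands`` assigns the strand of the circRNA associated with each peak:
    one symbol for all peaks, or a sequence aligned with ``peaks``.  Peaks
    whose extended window would leave the chromosome are skipped.
    """
    if isinstance(strands, str):
        strands = [strands] * len(peaks)
    if len(strands) != len(peaks):
        raise ValueError("one strand per peak required")
    out: list[SummitWindow] = []
    for p, strand in zip(peaks, strands):
        lo = p.summit - half - flank
        hi = p.summit + half + flank
        if lo < 0 or hi > _chrom_len(genome, p.chrom):
            continue
        seq = _fetch(genome, p.chrom, lo, hi)
        if strand == "-":
            seq = revcomp(seq)
        out.append(SummitWindow(chrom=p.chrom, summit=p.summit, strand=strand,
                                ext_sequence=seq, half=half, flank=flank))
    return out


def position_sequences(w: SummitWindow, flank: int | None = None) -> dict[int, str]:
    """Per-offset (2*flank + 1)-nt subsequences centered on each window position.

    Offsets whose full extent leaves the stored sequence are skipped (only
    possible when asking for a flank larger than the stored one).
    """
    flank = w.flank if flank is None else flank
    if flank > w.flank:
        raise ValueError("requested flank exceeds the stored sequence context")
    seqs: dict[int, str] = {}
    for off in w.offsets:
        center = w.flank + w.half + off  # index in ext_sequence
        seqs[off] = w.ext_sequence[center - flank : center + flank + 1]
    return seqs


@dataclass(frozen=True)
class ProfilePoint:
    offset: int
    mean_dG: float
    mean_gc: float
    n: int


def metaprofile(
    windows: Sequence[SummitWindow],
    backend: str = "builtin",
    flank: int | None = None,
) -> list[ProfilePoint]:
    """Mean folding dG and GC fraction per summit-relative offset."""
    if not windows:
        raise ValueError("at least one summit window required")
    acc_dg: dict[int, list[float]] = {}
    acc_gc: dict[int, list[float]] = {}
    if backend == "external":
        # batch all positions through one engine invocation
        offsets_per_w = [position_sequences(w, flank) for w in windows]
        all_seqs = [s for seqs in offsets_per_w for s in seqs.values()]
        energies = iter(_rnafold_mfe(all_seqs))
        for seqs in offsets_per_w:
            for off, s in seqs.items():
                acc_dg.setdefault(off, []).append(min(0.0, next(energies)))
                acc_gc.setdefault(off, []).append(gc_content(s))
    else:
        for w in windows:
            for off, s in position_sequences(w, flank).items():
                acc_dg.setdefault(off, []).append(fold_dG(s, backend=backend))
                acc_gc.setdefault(off, []).append(gc_content(s))
    points = [
        ProfilePoint(
            offset=off,
            mean_dG=float(np.mean(acc_dg[off])),
            mean_gc=float(np.nanmean(acc_gc[off])),
            n=len(acc_dg[off]),
        )
        for off in sorted(acc_dg)
    ]
    return points
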