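"""Intermolecular RNA-RNA hybridization energy.

An orthogonal metric to the point-based 3'-pairing score: the minimum free
energy (MFE) of hybridizing the miRNA 3' region with the upstream site
window, considering intermolecular pairs only (no intramolecular structure).

The builtin model is a reduced nearest-neighbor set — WCF and G:U stacking
energies shipped as a packaged table, affine bulge/internal-loop penalties,
a duplex initiation term, and a terminal penalty for helix ends closed by
weak (AU/GU) pairs.  It is built for ranking candidate sites, not for
thermodynamic fidelity: dangling ends and coaxial stacking are omitted.
When a ViennaRNA ``RNAduplex`` executable is available it can be selected as
an alternate backend, whose energies are then reported verbatim.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

from .io_formats import RNA_ALPHABET, MatureMiRNA, TranscriptRegion
from .pairing_score import ScoreParams, pair_class, site_window
from .seed_scan import SeedMatch

#: largest unpaired stretch considered on either side of an interior loop
MAX_LOOP = 10


@dataclass(frozen=True)
class DuplexResult:
    """An intermolecular structure: energy plus its (i, j) paired positions,
    0-based into the two input sequences."""

    energy: float
    pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class EnergyModel:
    """Reduced nearest-neighbor duplex parameters (kcal/mol).

    ``stack_energies`` maps (5' pair, 3' pair) to a stacking free energy,
    where a pair is written ``<top base><bottom base>``; the table must be
    complete over WCF+GU pairs and WCF/WCF entries must be favorable (<= 0).
    Loop costs are affine: ``bulge_open + bulge_ext*(n-1)`` for an n-nt
    bulge, ``iloop_open + iloop_ext*(n1+n2) + iloop_asym*|n1-n2|`` for an
    n1 x n2 interior loop.
    """

    stack_energies: Mapping[tuple[str, str], float]
    duplex_initiation: float = 4.09
    terminal_au_penalty: float = 0.45
    bulge_open: float = 3.8
    bulge_ext: float = 0.5
    iloop_open: float = 1.7
    iloop_ext: float = 0.5
    iloop_asym: float = 0.3

    def __post_init__(self) -> None:
        pairs = ("AU", "UA", "GC", "CG", "GU", "UG")
        for p1 in pairs:
            for p2 in pairs:
                if (p1, p2) not in self.stack_energies:
                    raise ValueError(f"stack table incomplete: missing {p1}/{p2}")
        wcf = ("AU", "UA", "GC", "CG")
        for p1 in wcf:
            for p2 in wcf:
                if self.stack_energies[(p1, p2)] > 0:
                    raise ValueError(f"WCF/WCF stack {p1}/{p2} must be <= 0")
        for name in ("terminal_au_penalty", "bulge_open", "bulge_ext",
                     "iloop_open", "iloop_ext", "iloop_asym"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def terminal(self, top: str, bottom: str) -> float:
        """Penalty for a helix end closed by an AU or GU pair."""
        return 0.0 if top + bottom in ("GC", "CG") else self.terminal_au_penalty

    def loop(self, di: int, dj: int) -> float:
        """Cost of the unpaired stretch (di on one strand, dj on the other)
        between two consecutive pairs; (0, 0) means a stack (cost handled
        separately)."""
        if di == 0 and dj == 0:
            return 0.0
        if di == 0 or dj == 0:
            n = di + dj
            return self.bulge_open + self.bulge_ext * (n - 1)
        return (self.iloop_open + self.iloop_ext * (di + dj)
                + self.iloop_asym * abs(di - dj))


def load_default_model() -> EnergyModel:
    """Load the packaged stacking-energy table."""
    table: dict[tuple[str, str], float] = {}
    text = (resources.files("tdmd_scout") / "data" / "stack_energies.tsv").read_text()
    lines = text.strip().splitlines()
    for line in lines[1:]:
        p1, p2, dg = line.split("\t")
        table[(p1, p2)] = float(dg)
    return EnergyModel(stack_energies=table)


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_default_model()
    return _DEFAULT_MODEL


def duplex_mfe(
    seq_a: str, seq_b: str, model: EnergyModel | None = None
) -> DuplexResult | None:
    """Minimum free energy of intermolecular hybridization of two RNAs.

    Both sequences are given 5'->3'; pairs are antiparallel (increasing
    position in ``seq_a`` against decreasing position in ``seq_b``).
    Returns ``None`` (the no-duplex sentinel) when no structure is more
    favorable than initiation alone.
    """
    model = model or default_model()
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{name}: non-RNA characters {sorted(bad)}")
    n, m = len(seq_a), len(seq_b)
    stacks = model.stack_energies
    INF = math.inf

    # D[i][j]: best energy of the duplex portion whose 5'-most pair in seq_a
    # is (i, j), including the terminal penalty at the far (3'-in-a) end.
    D = [[INF] * m for _ in range(n)]
    trace: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    pairable = [[pair_class(seq_a[i], seq_b[j]) is not None for j in range(m)]
                for i in range(n)]
    for i in range(n - 1, -1, -1):
        for j in range(m):
            if not pairable[i][j]:
                continue
            best = model.terminal(seq_a[i], seq_b[j])
            arg: tuple[int, int] | None = None
            p1 = seq_a[i] + seq_b[j]
            for k in range(i + 1, min(n, i + 2 + MAX_LOOP)):
                for l in range(max(-1, j - 2 - MAX_LOOP), j):
                    if l < 0 or not pairable[k][l] or D[k][l] is INF:
                        continue
                    di, dj = k - i - 1, j - l - 1
                    if di == 0 and dj == 0:
                        cost = stacks[(p1, seq_a[k] + seq_b[l])]
                    else:
                        cost = model.loop(di, dj)
                    cand = cost + D[k][l]
                    if cand < best:
                        best = cand
                        arg = (k, l)
            D[i][j] = best
            trace[i][j] = arg

    best_e = INF
    best_ij: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m):
            if D[i][j] is INF:
                continue
            e = model.duplex_initiation + model.terminal(seq_a[i], seq_b[j]) + D[i][j]
            if e < best_e:
                best_e, best_ij = e, (i, j)

    if best_ij is None or best_e >= model.duplex_initiation:
        return None
    pairs = []
    ij: tuple[int, int] | None = best_ij
    while ij is not None:
        pairs.append(ij)
        ij = trace[ij[0]][ij[1]]
    return DuplexResult(energy=round(best_e, 2), pairs=tuple(pairs))


def rnaduplex_available() -> bool:
    return shutil.which("RNAduplex") is not None


def duplex_mfe_external(seq_a: str, seq_b: str) -> DuplexResult | None:
    """MFE via the external ``RNAduplex`` executable (reported verbatim)."""
    proc = subprocess.run(
        ["RNAduplex", "--noconv"],
        input=f"{seq_a}\n{seq_b}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    # e.g. ".((((&)))).   3,6   :   1,4  (-5.40)"
    structure, rest = line.split(None, 1)
    energy = float(rest.rsplit("(", 1)[1].rstrip(")").strip())
    a_part, b_part = structure.split("&")
    a_range = rest.split(":")[0].split()[-1]
    b_range = rest.split(":")[1].split()[0]
    a_lo = int(a_range.split(",")[0])
    b_lo = int(b_range.split(",")[0])
    a_pos = [a_lo - 1 + k for k, c in enumerate(a_part) if c == "("]
    b_pos = [b_lo - 1 + k for k, c in enumerate(b_part) if c == ")"]
    pairs = tuple(zip(a_pos, reversed(b_pos)))
    if not pairs:
        return None
    return DuplexResult(energy=energy, pairs=pairs)


def energy_for_candidate(
    mirna: MatureMiRNA,
    match: SeedMatch,
    region: TranscriptRegion,
    params: ScoreParams | None = None,
    model: EnergyModel | None = None,
    backend: str = "builtin",
) -> float | None:
    """Hybridization MFE (kcal/mol) of the miRNA 3' region against the same
    upstream window used by the pairing scorer; ``None`` when the window is
    empty or no duplex forms."""
    params = params or ScoreParams()
    window, _ = site_window(match, region, params)
    if not window:
        return None
    three_prime = mirna.sequence[params.three_prime_start - 1 :]
    if backend == "external":
        result = duplex_mfe_external(three_prime, window)
    elif backend == "builtin":
        result = duplex_mfe(three_prime, window, model)
    else:
        raise ValueError(f"unknown energy backend {backend!r}")
    return None if result is None else result.energy
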