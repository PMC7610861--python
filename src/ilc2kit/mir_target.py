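"""miRNA seed-site scanning, duplex minimum-free-energy scoring and
seed mutagenesis.

Canonical target sites are defined by Watson-Crick complementarity of
the miRNA seed (positions 2-7, 1-based from the 5' end) to the 3'UTR:
a bare match is a 6mer; a match extended by complementarity to miRNA
position 8 (on the 5' side of the site as read on the UTR) is a
7mer-m8; an adenosine opposite miRNA position 1 (3' side of the site)
is a 7mer-A1; both extensions give an 8mer.  G.U wobbles are not
accepted in the seed match.

Hybridization stability is scored by a dynamic program over
intermolecular base pairing only (no intramolecular structure):
nearest-neighbor stack energies, length-dependent bulge and internal
loop penalties, a duplex-initiation term and terminal AU/GU penalties,
all read from a versioned parameter table shipped as package data.
Pair lists are antiparallel (indices strictly increasing on the miRNA,
strictly decreasing on the target) and pseudoknot-free by
construction.  UTR coordinates are 0-based half-open; miRNA positions
in prose are 1-based 5'->3' to match seed nomenclature.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

_RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_CAN_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
             ("G", "U"), ("U", "G")}
_WEAK_PAIR = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: r for r, c in enumerate(SEED_CLASSES)}


class RnaFormatError(ValueError):
    """Raised for sequences outside the A/C/G/U alphabet."""


@dataclass
class RnaSeq:
    """An RNA sequence, 5'->3'.  DNA-style T is converted to U."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = str(self.seq).upper().replace("T", "U")
        if not self.seq:
            raise RnaFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _RNA
        if bad:
            raise RnaFormatError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SeedSite:
    """A canonical seed match on a UTR, 0-based half-open interval."""

    utr_id: str
    start: int
    end: int
    site_class: str
    matched: str


@dataclass
class DuplexResult:
    """A miRNA:target hybridization: MFE in kcal/mol, base pairs as
    (miR index, target index) 0-based tuples, and a 4-line rendered
    alignment."""

    mfe: float
    pairing: list[tuple[int, int]]
    alignment: str = ""


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# FASTA helpers (plain text, two-line or wrapped records)


def read_fasta(path) -> list[RnaSeq]:
    records: list[RnaSeq] = []
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append(RnaSeq(id=name, seq="".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        records.append(RnaSeq(id=name, seq="".join(chunks)))
    return records


def write_fasta(records: list[RnaSeq], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for k in range(0, len(r.seq), 70):
                fh.write(r.seq[k : k + 70] + "\n")


# ---------------------------------------------------------------------------
# seed scanning


def scan_seed_sites(utr: RnaSeq, mir: RnaSeq,
                    classes=frozenset(SEED_CLASSES)) -> list[SeedSite]:
    """Find every canonical seed match of ``mir`` in ``utr``.

    Each occurrence of the reverse complement of miRNA positions 2-7
    is classified by its extensions (position-8 complement on the 5'
    flank, A on the 3' flank) and reported if its class is requested.
    Sites are sorted by start, ties broken longer class first.
    """
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt for seed scanning")
    bad = set(classes) - set(SEED_CLASSES)
    if bad:
        raise ValueError(f"unknown site classes {sorted(bad)}")
    core = revcomp(mir.seq[1:7])
    m8_comp = _COMPLEMENT[mir.seq[7]]
    u = utr.seq
    sites = []
    pos = u.find(core)
    while pos != -1:
        has_m8 = pos - 1 >= 0 and u[pos - 1] == m8_comp
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            cls, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            cls, start, end = "7mer-A1", pos, pos + 7
        else:
            cls, start, end = "6mer", pos, pos + 6
        if cls in classes:
            sites.append(SeedSite(utr_id=utr.id, start=start, end=end,
                                  site_class=cls, matched=u[start:end]))
        pos = u.find(core, pos + 1)
    sites.sort(key=lambda s: (s.start, -_CLASS_RANK[s.site_class]))
    return sites


# ---------------------------------------------------------------------------
# duplex MFE dynamic program


@lru_cache(maxsize=4)
def load_energy_params(params: str = "turner2004-like") -> dict:
    """Load and symmetrize the nearest-neighbor parameter table."""
    if params in ("turner2004-like", "default"):
        text = (
            importlib.resources.files("ilc2kit")
            .joinpath("data/nn_energies.json")
            .read_text()
        )
    else:
        text = Path(params).read_text()
    raw = json.loads(text)
    stack = dict(raw["stack"])
    for key, val in list(stack.items()):
        x, y, _, z, w = key
        flipped = f"{w}{z}/{y}{x}"
        stack.setdefault(flipped, val)
    raw["stack"] = stack
    raw["bulge"] = {int(k): v for k, v in raw["bulge"].items()}
    raw["internal"] = {int(k): v for k, v in raw["internal"].items()}
    return raw


def _loop_penalty(table: dict, size: int, kind: str) -> float:
    tab = table[kind]
    if size in tab:
        return tab[size]
    base = max(tab)
    return tab[base] + table["loop_extrapolation_coef"] * np.log(size / base)


def _gap_energy(table, mir, tgt, i1, j1, i2, j2) -> float | None:
    """Energy of moving from pair (i1, j1) to pair (i2, j2); None if
    the gap exceeds the loop-length limit."""
    li, lj = i2 - i1 - 1, j1 - j2 - 1
    if li == 0 and lj == 0:
        return table["stack"].get(f"{mir[i1]}{mir[i2]}/{tgt[j1]}{tgt[j2]}")
    if li == 0 or lj == 0:
        return _loop_penalty(table, li + lj, "bulge")
    pen = _loop_penalty(table, li + lj, "internal")
    pen += min(table["internal_asymmetry"] * abs(li - lj),
               table["internal_asymmetry_max"])
    return pen


def _terminal(table, a: str, b: str) -> float:
    return table["terminal_au"] if (a, b) in _WEAK_PAIR else 0.0


def duplex_mfe(mir: RnaSeq, target: RnaSeq,
               params: str = "turner2004-like",
               max_loop: int = 15) -> DuplexResult:
    """Minimum free energy of intermolecular hybridization between
    ``mir`` and ``target``.

    Dynamic program over antiparallel pair chains: consecutive pairs
    are joined by a stack (nearest-neighbor energy), a bulge or an
    internal loop with at most ``max_loop`` unpaired bases per strand.
    Duplex initiation and terminal AU/GU penalties come from the
    parameter table.  The empty duplex scores 0, so the MFE is never
    positive.  Ties are broken toward fewer pairs, then the smallest
    miRNA start index.
    """
    if max_loop < 0:
        raise ValueError("max_loop must be >= 0")
    table = load_energy_params(params)
    m, t = mir.seq, target.seq
    n, L = len(m), len(t)
    init = table["duplex_init"]
    NEG = 1e-9

    # E[i][j]: best energy of a chain ending with pair (i, j), opening
    # terminal penalty and initiation included.  Value = (energy,
    # n_pairs, first miR index, backpointer).
    E: dict[tuple[int, int], tuple[float, int, int, tuple | None]] = {}
    order = []
    for i in range(n):
        for j in range(L - 1, -1, -1):
            if (m[i], t[j]) not in _CAN_PAIR:
                continue
            best = (init + _terminal(table, m[i], t[j]), 1, i, None)
            for i1 in range(max(0, i - max_loop - 1), i):
                for j1 in range(j + 1, min(L, j + max_loop + 2)):
                    prev = E.get((i1, j1))
                    if prev is None:
                        continue
                    g = _gap_energy(table, m, t, i1, j1, i, j)
                    if g is None:
                        continue
                    cand = (prev[0] + g, prev[1] + 1, prev[2], (i1, j1))
                    if (cand[0] < best[0] - NEG
                            or (abs(cand[0] - best[0]) <= NEG
                                and (cand[1], cand[2]) < (best[1], best[2]))):
                        best = cand
            E[(i, j)] = best
            order.append((i, j))

    closed = (0.0, 0, n, None)  # empty duplex
    close_at = None
    for (i, j) in order:
        e, npairs, start, _ = E[(i, j)]
        total = e + _terminal(table, m[i], t[j])
        cand = (total, npairs, start)
        if (cand[0] < closed[0] - NEG
                or (abs(cand[0] - closed[0]) <= NEG
                    and (cand[1], cand[2]) < (closed[1], closed[2]))):
            closed = (total, npairs, start, None)
            close_at = (i, j)

    if close_at is None or closed[0] >= -NEG:
        return DuplexResult(mfe=0.0, pairing=[], alignment="")

    pairing = []
    node = close_at
    while node is not None:
        pairing.append(node)
        node = E[node][3]
    pairing.reverse()
    return DuplexResult(mfe=float(closed[0]), pairing=pairing,
                        alignment=render_alignment(mir, target, pairing))


def render_alignment(mir: RnaSeq, target: RnaSeq,
                     pairing: list[tuple[int, int]]) -> str:
    """Render a duplex as a fixed 4-line text block: target (5'->3')
    and miRNA (3'->5') with paired bases pulled onto the two inner
    lines, in the style of hybridization tools."""
    if not pairing:
        return ""
    m, t = mir.seq, target.seq
    l_top, l_tp, l_mp, l_bot = [], [], [], []

    def emit(tc: str, tp: str, mp: str, mc: str) -> None:
        l_top.append(tc)
        l_tp.append(tp)
        l_mp.append(mp)
        l_bot.append(mc)

    # target runs 5'->3' on top; miRNA 3'->5' on the bottom, so walk
    # pairs from the last (smallest target index is at the chain end)
    pairs = sorted(pairing, key=lambda p: p[1])  # ascending target idx
    mir_idx = [p[0] for p in pairs]  # descending miR idx
    ti = pairs[0][1]
    # 5' unpaired target context (up to 6 nt)
    lead_t = t[max(0, ti - 6):ti]
    lead_m = m[mir_idx[0] + 1:]
    pad = max(len(lead_t), len(lead_m[::-1]))
    emit_str = lambda s, n: " " * (n - len(s)) + s
    for a, b in zip(emit_str(lead_t, pad), emit_str(lead_m[::-1], pad)):
        emit(a, " ", " ", b)
    prev_i, prev_j = None, None
    for (i, j) in pairs:
        if prev_j is not None:
            gap_t = t[prev_j + 1:j]
            gap_m = m[i + 1:prev_i][::-1]
            width = max(len(gap_t), len(gap_m))
            gt = gap_t.ljust(width)
            gm = gap_m.ljust(width)
            for a, b in zip(gt, gm):
                emit(a, " ", " ", b)
        emit(" ", t[j], m[i], " ")
        prev_i, prev_j = i, j
    tail_t = t[prev_j + 1:prev_j + 7]
    tail_m = m[:pairs[-1][0]][::-1]
    width = max(len(tail_t), len(tail_m))
    for a, b in zip(tail_t.ljust(width), tail_m.ljust(width)):
        emit(a, " ", " ", b)
    return "\n".join([
        "target 5' " + "".join(l_top) + " 3'",
        "          " + "".join(l_tp),
        "          " + "".join(l_mp),
        "miRNA  3' " + "".join(l_bot) + " 5'",
    ])


# ---------------------------------------------------------------------------
# seed mutagenesis


def mutate_seed(utr: RnaSeq, site: SeedSite, mir: RnaSeq,
                seed: int = 0, flank: int = 10) -> RnaSeq:
    """Abolish a canonical seed site by minimal substitution.

    Replaces up to 3 bases of the seed-match core so that (a)
    re-scanning the mutated UTR finds no canonical site of any class
    overlapping the original interval, and (b) hybridization of the
    miRNA to the site ± ``flank`` nt is not made more stable — a
    substitution that breaks the seed can by chance create new
    complementarity to another miRNA position, which a designed
    mutant must avoid.  Deterministic given ``seed``.
    """
    if not (0 <= site.start < site.end <= len(utr.seq)):
        raise ValueError("site does not lie within the UTR")
    core_start = site.start + (1 if site.site_class in ("7mer-m8", "8mer") else 0)
    lo = max(0, site.start - flank)
    hi = min(len(utr.seq), site.end + flank)
    e_wt = duplex_mfe(mir, RnaSeq("w", utr.seq[lo:hi])).mfe
    rng = np.random.default_rng(seed)
    positions = list(range(core_start + 1, core_start + 5))  # middle of core
    for n_sub in (2, 3):
        for _ in range(200):
            chosen = sorted(rng.choice(positions, size=n_sub, replace=False))
            seq = list(utr.seq)
            for p in chosen:
                # avoid bases that could still pair (incl. wobble) with
                # the miR base opposite this core position
                opposite = _COMPLEMENT[seq[p]]
                options = [b for b in "ACGU"
                           if b != seq[p] and (b, opposite) not in _CAN_PAIR]
                seq[p] = options[int(rng.integers(len(options)))]
            mutated = RnaSeq(id=utr.id + "_mut", seq="".join(seq))
            hits = scan_seed_sites(mutated, mir)
            if any(h.start < site.end and h.end > site.start for h in hits):
                continue
            e_mut = duplex_mfe(mir, RnaSeq("w", mutated.seq[lo:hi])).mfe
            if e_mut >= e_wt - 1e-9:
                return mutated
    raise RuntimeError("could not abolish the seed site within 3 substitutions")
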