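"""Osmium-taggable hybridization probes for nanopore miRNA sensing.

A probe is an oligodeoxynucleotide whose core is the reverse complement of
the target miRNA.  Because osmium tetroxide-bipyridine (OsBp) reacts much
faster with T than with U or C, every T in the core is substituted by
2'-deoxyuridine (dU) or 2'-OMe-uridine (mU), and a block of five adjacent
Ts appended 3' of the core carries the osmium tags that slow translocation
and make the probe visible to the pore.  A-tails of 4-6 nt at either end
ease pore entry; an optional single spacer residue may sit before or after
the tag block.

Layout:   5'-(A)left - core(revcomp, T->dU/mU) - [spacer] - (T)5 - [spacer] - (A)right-3'
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "Residue",
    "ProbeSequence",
    "KNOWN_PROBES",
    "SequenceError",
    "design_probe",
    "parse_probe_notation",
    "verify_complementarity",
    "osmylation_extent",
    "osmylation_ratio",
    "taggable_census",
]

TAG_BLOCK_LENGTH = 5
PYRIMIDINES = {"C", "T", "U"}


class SequenceError(ValueError):
    """Input sequence uses an invalid alphabet or length."""


@dataclass(frozen=True)
class Residue:
    """One probe residue: base letter, sugar chemistry, and taggability.

    ``taggable`` marks fast OsBp kinetics (the T tag block); U/dU/mU and C
    react slowly and normally stay untagged.
    """

    base: str  # A, C, G, T, U
    chemistry: str  # "DNA", "dU", "2'-OMe"
    taggable: bool


@dataclass
class ProbeSequence:
    """An annotated probe with its region structure."""

    residues: list[Residue]
    left_tail: int
    core_length: int
    right_tail: int
    spacer_before_tag: str = ""
    spacer_after_tag: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def core(self) -> list[Residue]:
        start = self.left_tail
        return self.residues[start:start + self.core_length]

    def core_string(self, normalize_u: bool = True) -> str:
        """Core letters; with ``normalize_u`` dU/mU are written as U."""
        out = []
        for r in self.core:
            if normalize_u and r.chemistry in ("dU", "2'-OMe") and r.base in ("T", "U"):
                out.append("U")
            else:
                out.append(r.base)
        return "".join(out)

    def to_notation(self) -> str:
        """Render in the compact tail notation, e.g. (A)6dUG...(T)5(A)6."""
        parts = [f"(A){self.left_tail}"] if self.left_tail else []
        # self.core already spans any spacer interposed before the tag block
        for r in self.core:
            if r.chemistry == "dU":
                parts.append("dU")
            elif r.chemistry == "2'-OMe":
                parts.append("mU")
            else:
                parts.append(r.base)
        parts.append(f"(T){TAG_BLOCK_LENGTH}")
        parts.append(self.spacer_after_tag)
        if self.right_tail:
            parts.append(f"(A){self.right_tail}")
        return "".join(parts)


#: Published probe set (tail notation, concentration fM, measured mean OsBp tags).
KNOWN_PROBES: dict[str, tuple[str, float, float]] = {
    "Probe15b": ("(A)6dUGdUAAACCAdUGAdUGdUGCdUGCdUA(T)5(A)6", 43.4, 5.9),
    "Probe21": ("(A)5dUCAACAdUCAGdUCdUGAdUAAGCdUA(T)5C(A)6", 36.6, 6.2),
    "Probe375": ("(A)5dUCACGCGAGCCGAACGAACAAAC(T)5C(A)5", 41.6, 5.9),
    "Probe141": ("(A)4CCAmUCmUmUmUACCAGACAGmUGmUmUA(T)5(A)5", 39.0, 6.3),
}


def _check_rna(target_rna: str) -> str:
    seq = target_rna.strip().upper().replace("T", "U")
    if not re.fullmatch(r"[ACGU]+", seq):
        raise SequenceError(f"target must be RNA over A/C/G/U, got {target_rna!r}")
    return seq


def design_probe(
    target_rna: str,
    left_tail: int = 5,
    right_tail: int = 5,
    chemistry: str = "dU",
    spacer_before_tag: str = "",
    spacer_after_tag: str = "",
) -> ProbeSequence:
    """Construct a probe for ``target_rna``.

    The core is the DNA reverse complement of the target with every T
    replaced by dU (``chemistry="dU"``) or 2'-OMe-U (``chemistry="2'-OMe"``).
    Tail lengths of 4-6 match the published designs; the optional spacer
    residues reproduce layouts that interpose a C around the tag block.
    """
    seq = _check_rna(target_rna)
    if not 15 <= len(seq) <= 30:
        raise SequenceError(f"target length {len(seq)} outside 15-30 nt")
    if not (4 <= left_tail <= 6 and 4 <= right_tail <= 6):
        raise SequenceError("A-tails must be 4-6 nt")
    if chemistry not in ("dU", "2'-OMe"):
        raise SequenceError(f"unknown core chemistry {chemistry!r}")
    core_dna = str(Seq(seq).back_transcribe().reverse_complement())
    residues = [Residue("A", "DNA", False)] * left_tail
    for base in core_dna:
        if base == "T":
            residues.append(Residue("U", chemistry, False))
        else:
            residues.append(Residue(base, "DNA", False))
    for base in spacer_before_tag:
        residues.append(Residue(base.upper(), "DNA", False))
    residues += [Residue("T", "DNA", True)] * TAG_BLOCK_LENGTH
    for base in spacer_after_tag:
        residues.append(Residue(base.upper(), "DNA", False))
    residues += [Residue("A", "DNA", False)] * right_tail
    return ProbeSequence(
        residues=residues,
        left_tail=left_tail,
        core_length=len(core_dna) + len(spacer_before_tag),
        right_tail=right_tail,
        spacer_before_tag=spacer_before_tag,
        spacer_after_tag=spacer_after_tag,
    )


_TOKEN = re.compile(r"\(([ACGT])\)_?(\d+)_?|dU|mU|[ACGT]")


def parse_probe_notation(notation: str) -> ProbeSequence:
    """Parse the compact tail notation, e.g. ``(A)6dUG...(T)5C(A)6``.

    Underscore-decorated repeat counts (``(A)_6_``) are accepted.  Regions
    are inferred: the leading A-run is the left tail, the trailing A-run the
    right tail, the (T)5 group the tag block; anything between tag block and
    right tail is a spacer, anything between left tail and tag block the
    core (with a trailing spacer C, if present, folded into the core just as
    printed).
    """
    s = notation.replace(" ", "")
    residues: list[Residue] = []
    groups: list[tuple[str, int, int]] = []  # (kind, start_index, length)
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m:
            raise SequenceError(f"cannot parse probe notation at {s[pos:]!r}")
        tok = m.group(0)
        if tok.startswith("("):
            base, count = m.group(1), int(m.group(2))
            groups.append((f"run:{base}", len(residues), count))
            residues += [Residue(base, "DNA", base == "T")] * count
        elif tok == "dU":
            residues.append(Residue("U", "dU", False))
        elif tok == "mU":
            residues.append(Residue("U", "2'-OMe", False))
        else:
            residues.append(Residue(tok, "DNA", False))
        pos = m.end()

    tag_groups = [g for g in groups if g[0] == "run:T" and g[2] == TAG_BLOCK_LENGTH]
    if not tag_groups:
        raise SequenceError("no (T)5 tag block found")
    tag_start = tag_groups[-1][1]
    a_runs = [g for g in groups if g[0] == "run:A"]
    left = a_runs[0][2] if a_runs and a_runs[0][1] == 0 else 0
    right = (
        a_runs[-1][2]
        if a_runs and a_runs[-1][1] + a_runs[-1][2] == len(residues)
        else 0
    )
    spacer_after = "".join(
        r.base for r in residues[tag_start + TAG_BLOCK_LENGTH:len(residues) - right]
    )
    return ProbeSequence(
        residues=residues,
        left_tail=left,
        core_length=tag_start - left,
        right_tail=right,
        spacer_before_tag="",
        spacer_after_tag=spacer_after,
    )


def _pairs(a: str, b: str) -> bool:
    """Watson-Crick complement test with T and U equivalent."""
    wc = {"A": "TU", "T": "A", "U": "A", "G": "C", "C": "G"}
    return b in wc.get(a, "")


def verify_complementarity(probe: ProbeSequence, target_rna: str) -> int:
    """Longest contiguous Watson-Crick duplex between probe and target.

    The target is reverse-complemented and slid along the probe (dU and
    2'-OMe-U pair like U); the maximum run of consecutive matches is
    returned.  A full-length core match equals the target length.
    """
    seq = _check_rna(target_rna)
    probe_letters = [
        "U" if (r.chemistry in ("dU", "2'-OMe") and r.base in ("T", "U")) else r.base
        for r in probe.residues
    ]
    target_rev = seq[::-1]
    n, m = len(probe_letters), len(target_rev)
    best = 0
    for offset in range(-(m - 1), n):
        run = 0
        for j in range(m):
            i = offset + j
            if 0 <= i < n and _pairs(target_rev[j], probe_letters[i]):
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def osmylation_extent(r_312_272: float, total_nt: int) -> float:
    """Average OsBp tags from the absorbance ratio: tags = R x nt / 2."""
    if r_312_272 < 0:
        raise ValueError("absorbance ratio must be >= 0")
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    return r_312_272 * total_nt / 2.0


def osmylation_ratio(avg_tags: float, total_nt: int) -> float:
    """Inverse of :func:`osmylation_extent`: R(312/272) = 2 x tags / nt."""
    if avg_tags < 0:
        raise ValueError("avg_tags must be >= 0")
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    return 2.0 * avg_tags / total_nt


def taggable_census(probe: ProbeSequence, extra_internal: bool = False) -> dict:
    """Count fast (T) vs slow (U/dU/mU/C) pyrimidines and expected tags.

    The expected tag count equals the fast-T count; HPLC routinely shows
    about one extra tag on an internal C or U (``extra_internal``).
    """
    fast = sum(1 for r in probe.residues if r.base == "T")
    slow_u = sum(1 for r in probe.residues if r.base == "U")
    slow_c = sum(1 for r in probe.residues if r.base == "C")
    return {
        "fast_T": fast,
        "slow_U": slow_u,
        "slow_C": slow_c,
        "pyrimidines": fast + slow_u + slow_c,
        "expected_tags": fast + (1 if extra_internal else 0),
    }
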