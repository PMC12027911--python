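"""Cohort scoring and the multi-test screening error model.

Each sample x miRNA cell of a cohort table holds one or more binary test
outcomes: meets expectation ("nu"), fails it ("X"), or not determined
("ND").  The expectation is fixed by the biology: a non-biomarker miRNA
(miR-15b) stays below 1.5 HL in every sample, while the cancer biomarkers
(miR-21, miR-375, miR-141) exceed 1.5 HL only in cancer samples.  Scores
count every individual outcome (multi-outcome cells contribute each entry)
and exclude ND.

For population screening, a subject is assigned only when k independent
tests agree; with single-test true rate p the expected false assignments
in a population N are N(1-p)^k, and with three tests the chance that two
agree while the third differs is 3p(1-p).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortTable",
    "ExpectationRule",
    "DEFAULT_EXPECTATIONS",
    "load_cohort_table",
    "score_column",
    "score_group",
    "false_assignment",
    "majority_disagreement",
    "sensitivity_gain",
    "parse_molarity",
]

MEETS = "nu"
FAILS = "X"
NOT_DETERMINED = "ND"

#: outcome-symbol normalization; the Greek capital nu occasionally appears
#: in printed tables and is folded into the lowercase form
_SYMBOLS = {"ν": MEETS, "Ν": MEETS, "v": MEETS, "nu": MEETS,
            "x": FAILS, "X": FAILS, "nd": NOT_DETERMINED, "ND": NOT_DETERMINED}


@dataclass(frozen=True)
class ExpectationRule:
    """Expected side of the 1.5 HL threshold per miRNA and group."""

    expected_side: dict[str, dict[str, str]]  # miRNA -> group -> "above"|"below"

    def side(self, mirna: str, group: str) -> str:
        return self.expected_side[mirna][group]


DEFAULT_EXPECTATIONS = ExpectationRule(
    expected_side={
        "miR-15b": {"cancer": "below", "healthy": "below"},
        "miR-21": {"cancer": "above", "healthy": "below"},
        "miR-375": {"cancer": "above", "healthy": "below"},
        "miR-141": {"cancer": "above", "healthy": "below"},
    }
)


@dataclass
class CohortTable:
    """Samples x miRNAs with per-cell outcome lists."""

    samples: pd.DataFrame  # sample_id, group, indication, specimen
    outcomes: dict[str, list[list[str]]]  # miRNA -> per-sample outcome lists

    @property
    def mirnas(self) -> list[str]:
        return list(self.outcomes)

    def group_rows(self, group: str) -> list[int]:
        rows = [i for i, g in enumerate(self.samples["group"]) if g == group]
        if not rows:
            raise ValueError(f"group {group!r} not present")
        return rows


def _parse_cell(cell: str) -> list[str]:
    if not isinstance(cell, str) or not cell.strip():
        return []
    out = []
    for token in re.split(r"[;,]", cell):
        token = token.strip()
        if not token:
            continue
        try:
            out.append(_SYMBOLS[token])
        except KeyError:
            raise ValueError(f"unknown outcome symbol {token!r}") from None
    return out


def load_cohort_table(path: str | Path | None = None) -> CohortTable:
    """Load a cohort CSV; defaults to the packaged training-cohort table."""
    if path is None:
        source = resources.files("nanosense").joinpath("data/table1_cohort.csv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str)
    meta_cols = ["sample_id", "group", "indication", "specimen"]
    missing = [c for c in meta_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    mirna_cols = [c for c in frame.columns if c not in meta_cols]
    outcomes = {m: [_parse_cell(c) for c in frame[m]] for m in mirna_cols}
    return CohortTable(samples=frame[meta_cols].copy(), outcomes=outcomes)


def score_column(table: CohortTable, mirna: str) -> tuple[int, int, float]:
    """(meets, non-ND total, percent true) for one miRNA column."""
    if mirna not in table.outcomes:
        raise KeyError(f"miRNA {mirna!r} not in table")
    flat = [o for cell in table.outcomes[mirna] for o in cell if o != NOT_DETERMINED]
    total = len(flat)
    if total == 0:
        raise ValueError(f"no determined outcomes for {mirna}")
    meets = sum(1 for o in flat if o == MEETS)
    return meets, total, 100.0 * meets / total


def score_group(table: CohortTable, group: str) -> float:
    """Pooled fraction of outcomes meeting expectation over a sample group."""
    rows = table.group_rows(group)
    meets = total = 0
    for mirna in table.mirnas:
        for i in rows:
            for o in table.outcomes[mirna][i]:
                if o == NOT_DETERMINED:
                    continue
                total += 1
                meets += o == MEETS
    if total == 0:
        raise ValueError(f"no determined outcomes in group {group!r}")
    return meets / total


def false_assignment(p_true: float, k_tests: int, population: float) -> float:
    """Expected false assignments when assignment requires k concordant tests.

    Each test is independently true with probability ``p_true``; a subject
    is falsely assigned when all k tests err the same way, so the expected
    count in ``population`` subjects is population x (1-p)^k.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must lie in [0,1]")
    if k_tests < 1:
        raise ValueError("k_tests must be >= 1")
    if population < 0:
        raise ValueError("population must be >= 0")
    return population * (1.0 - p_true) ** k_tests


def majority_disagreement(p_true: float) -> float:
    """P(exactly two of three binary tests agree while the third differs).

    Equals 3p^2(1-p) + 3p(1-p)^2 = 3p(1-p); symmetric in p <-> 1-p and
    maximal at p = 1/2.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must lie in [0,1]")
    return 3.0 * p_true * (1.0 - p_true)


_MOLARITY_UNITS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9,
    "pM": 1e-12, "fM": 1e-15, "aM": 1e-18,
}


def parse_molarity(text: str) -> float:
    """Parse '50 pM' / '5fM' style concentrations to molar."""
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([munpfaμ]?M)\s*", str(text))
    if not m or m.group(2) not in _MOLARITY_UNITS:
        raise ValueError(f"cannot parse molarity {text!r}")
    return float(m.group(1)) * _MOLARITY_UNITS[m.group(2)]


def sensitivity_gain(dl_a: str | float, dl_b: str | float) -> float:
    """Fold improvement of detection limit b over a (dl_a / dl_b)."""
    a = parse_molarity(dl_a) if isinstance(dl_a, str) else float(dl_a)
    b = parse_molarity(dl_b) if isinstance(dl_b, str) else float(dl_b)
    if a <= 0 or b <= 0:
        raise ValueError("detection limits must be positive")
    return a / b
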