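"""Packaged reference activation tables and their verification.

The package ships the per-subject activation counts reported in the original
ten-subject evaluation of the two judgment approaches (Approach 1: SVM;
Approach 2: optimal-feature rules), in the published column layout.  The
verification below recomputes every subtotal row from the per-subject rows
and checks the stored subtotals and the subject-3 narrative counts against
them, so the printed summary numbers are reproducible from the raw rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from serj.adaptation import append_subtotals
from serj.errors import FormatError

_FIXTURES = {
    "approach1": "activation_counts_approach1.csv",
    "approach2": "activation_counts_approach2.csv",
}
_COLUMNS = ["subject", "participated_before", "HANV", "LAPV", "HAPV", "LANV"]


def load_reference_table(approach: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (per-subject rows, stored subtotal rows) for one approach."""
    if approach not in _FIXTURES:
        raise FormatError(f"unknown approach {approach!r}; use 'approach1' or 'approach2'")
    with resources.files("serj.data").joinpath(_FIXTURES[approach]).open() as fh:
        df = pd.read_csv(fh, dtype={"subject": str})
    if list(df.columns) != _COLUMNS:
        raise FormatError(f"fixture schema mismatch: {list(df.columns)}")
    is_total = df["subject"].str.startswith("total")
    return df[~is_total].reset_index(drop=True), df[is_total].reset_index(drop=True)


@dataclass(frozen=True)
class Claim:
    name: str
    expected: float
    computed: float

    @property
    def ok(self) -> bool:
        return self.expected == self.computed


@dataclass
class VerificationReport:
    claims: list[Claim]

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.claims)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"claim": c.name, "expected": c.expected, "computed": c.computed, "ok": c.ok}
                for c in self.claims
            ]
        )


def verify_reference_tables() -> VerificationReport:
    """Recompute all subtotal rows and the subject-3 counts from subject rows."""
    claims: list[Claim] = []
    for approach in ("approach1", "approach2"):
        subjects, stored = load_reference_table(approach)
        recomputed = append_subtotals(subjects)
        recomputed = recomputed[recomputed["subject"].str.startswith("total")]
        for _, stored_row in stored.iterrows():
            match = recomputed[recomputed["subject"] == stored_row["subject"]]
            for col in ("HANV", "LAPV", "LANV"):
                computed = float(match[col].iloc[0]) if len(match) else float("nan")
                claims.append(
                    Claim(
                        name=f"{approach}:{stored_row['subject']}:{col}",
                        expected=float(stored_row[col]),
                        computed=computed,
                    )
                )
    # subject-3 narrative: 8 activations under Approach 2, 2 of them LANV,
    # the other two event types 3 each
    subjects, _ = load_reference_table("approach2")
    s3 = subjects[subjects["subject"] == "3"].iloc[0]
    total = float(s3["HANV"] + s3["LAPV"] + s3["LANV"])
    claims.append(Claim("approach2:subject3:total", 8.0, total))
    claims.append(Claim("approach2:subject3:LANV", 2.0, float(s3["LANV"])))
    claims.append(Claim("approach2:subject3:HANV", 3.0, float(s3["HANV"])))
    claims.append(Claim("approach2:subject3:LAPV", 3.0, float(s3["LAPV"])))
    return VerificationReport(claims=claims)
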