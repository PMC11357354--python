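"""Reference tables of published NAD(P)H FLIM heterogeneity values.

Machine-readable copies of the published summary tables for colorectal
cancer: per-line decay parameters (cell lines in vitro and mouse tumors in
vivo), the bimodality index BI-a1 and dispersion D-a1 for four cell lines,
four mouse tumor types and 29 patient tumor samples, and the patient-cohort
clinical summary.  ``verify_fixture_claims`` recomputes the internally
checkable statements from these rows: the tau_m identity on the in-vitro
decay parameters, the count of highly heterogeneous patient tumors
(BI-a1 >= 1.1), and the extreme BI/D values in the patient cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .heterogeneity import categorize

__all__ = ["ReferenceTables", "FixtureCheck", "load_fixture", "verify_fixture_claims"]


@dataclass
class ReferenceTables:
    """The published summary tables as DataFrames."""

    decay_params: pd.DataFrame  # per-line tau_m, tau1, tau2, a1, BI-tau_m
    cell_lines: pd.DataFrame  # BI-a1 and D-a1 for the 4 cultured lines
    mouse_tumors: pd.DataFrame  # BI-a1 (mean+-sd) and D-a1 for 4 tumor types
    patients: pd.DataFrame  # BI-a1 and D-a1 for 29 patient samples
    clinical_summary: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.patients) != 29:
            raise ValueError(f"patient table must have 29 rows, got {len(self.patients)}")
        if self.patients["bi_a1"].isna().any() or self.patients["d_a1"].isna().any():
            raise ValueError("patient BI/D values must be complete")
        if len(self.cell_lines) != 4:
            raise ValueError("cell-line table must have 4 rows")


def _read(name: str) -> pd.DataFrame:
    with resources.files("flimhet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixture() -> ReferenceTables:
    return ReferenceTables(
        decay_params=_read("table1_decay_params.csv"),
        cell_lines=_read("table2_cell_lines.csv"),
        mouse_tumors=_read("table2_mouse_tumors.csv"),
        patients=_read("table2_patients.csv"),
        clinical_summary=_read("table3_clinical_summary.csv"),
    )


@dataclass
class FixtureCheck:
    name: str
    passed: bool
    observed: float | int | str
    expected: float | int | str


def verify_fixture_claims(fixture: ReferenceTables | None = None) -> list[FixtureCheck]:
    """Recompute the internally checkable claims from the reference tables.

    The tau_m identity is applied to the in-vitro rows only: the in-vivo rows
    are medians of per-cell quantities, and a median of ratios need not
    satisfy the ratio of medians row-wise.
    """
    fixture = fixture or load_fixture()
    checks: list[FixtureCheck] = []

    invitro = fixture.decay_params[fixture.decay_params["setting"] == "in_vitro"]
    for row in invitro.itertuples():
        recomputed = (row.a1 * row.tau1 + (100.0 - row.a1) * row.tau2) / 100.0
        checks.append(
            FixtureCheck(
                name=f"tau_m_identity_{row.cell_line}",
                passed=abs(recomputed - row.tau_m) <= 0.01,
                observed=round(recomputed, 4),
                expected=row.tau_m,
            )
        )

    bi = fixture.patients["bi_a1"].to_numpy()
    d = fixture.patients["d_a1"].to_numpy()
    n_bimodal = int((bi >= 1.1).sum())
    checks.append(
        FixtureCheck("patients_bimodal_count", n_bimodal == 14, n_bimodal, 14)
    )
    n_homog = int(sum(categorize(v) == "homogeneous" for v in bi))
    checks.append(FixtureCheck("patients_homogeneous_count", n_homog == 1, n_homog, 1))
    checks.append(
        FixtureCheck("patients_bi_min", np.isclose(bi.min(), 0.24), float(bi.min()), 0.24)
    )
    checks.append(
        FixtureCheck("patients_d_min", np.isclose(d.min(), 2.19), float(d.min()), 2.19)
    )
    checks.append(
        FixtureCheck("patients_d_max", np.isclose(d.max(), 11.99), float(d.max()), 11.99)
    )

    cl = fixture.cell_lines
    checks.append(
        FixtureCheck(
            "cell_lines_all_below_bimodal_cutoff",
            bool((cl["bi_a1"] < 1.1).all()),
            float(cl["bi_a1"].max()),
            "< 1.1",
        )
    )
    checks.append(
        FixtureCheck(
            "cell_lines_d_range",
            np.isclose(cl["d_a1"].min(), 1.67) and np.isclose(cl["d_a1"].max(), 3.41),
            f"{cl['d_a1'].min()}-{cl['d_a1'].max()}",
            "1.67-3.41",
        )
    )
    return checks
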