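"""Per-gene, per-branch substitution-rate tables with sentinel codes.

Free-ratio branch estimates are reported per gene and branch as dN, dS and
their ratio omega.  Two degenerate regimes get sentinel codes instead of a
number, following the conventions of published branch-rate tables:

``GT1``
    dS is effectively zero while dN exceeds the low-divergence threshold;
    the ratio is formally infinite and is reported only as "dN/dS > 1"
    (printed ``>1``), read as evidence of positive selection.
``LOWDIV``
    both dN and dS are below the low-divergence threshold (default 0.001);
    there is too little divergence to determine the ratio (printed ``-``).

Sentinel classification is a total function of (dN, dS, threshold): every
nonnegative pair maps to exactly one of VALUE / GT1 / LOWDIV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger("ovorate")

LOW_DIV_THRESHOLD = 0.001

GT1_TOKEN = ">1"
LOWDIV_TOKEN = "-"


class OmegaCode(str, Enum):
    VALUE = "VALUE"
    GT1 = "GT1"
    LOWDIV = "LOWDIV"


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class BranchRateRecord:
    """One gene x branch rate estimate, possibly a sentinel."""

    gene_id: str
    branch: str
    dN: float
    dS: float
    code: OmegaCode
    omega: float | None = None  # numeric ratio; None for sentinels

    def __post_init__(self):
        if self.code is OmegaCode.VALUE:
            if self.omega is None or not np.isfinite(self.omega) or self.omega < 0:
                raise ValueError(
                    f"VALUE record requires finite nonnegative omega, got {self.omega}"
                )
        elif self.omega is not None:
            raise ValueError(f"sentinel record {self.code} carries no numeric omega")

    @property
    def omega_token(self) -> str:
        if self.code is OmegaCode.GT1:
            return GT1_TOKEN
        if self.code is OmegaCode.LOWDIV:
            return LOWDIV_TOKEN
        return format(self.omega, "g")


def classify_rate(dN: float, dS: float, low_div_threshold: float = LOW_DIV_THRESHOLD) -> OmegaCode:
    """Classify a (dN, dS) pair into VALUE / GT1 / LOWDIV.

    LOWDIV: both rates below the threshold.  GT1: dS below the threshold
    but dN above it (ratio formally infinite).  Everything else is a VALUE.
    """
    if dN < 0 or dS < 0:
        raise ValueError(f"negative rate: dN={dN}, dS={dS}")
    if dN < low_div_threshold and dS < low_div_threshold:
        return OmegaCode.LOWDIV
    if dS < low_div_threshold:
        return OmegaCode.GT1
    return OmegaCode.VALUE


def make_record(
    gene_id: str,
    branch: str,
    dN: float,
    dS: float,
    low_div_threshold: float = LOW_DIV_THRESHOLD,
) -> BranchRateRecord:
    code = classify_rate(dN, dS, low_div_threshold)
    omega = dN / dS if code is OmegaCode.VALUE else None
    return BranchRateRecord(gene_id, branch, dN, dS, code, omega)


def parse_omega_token(token: str) -> tuple[OmegaCode, float | None]:
    token = token.strip()
    if token == GT1_TOKEN:
        return OmegaCode.GT1, None
    if token == LOWDIV_TOKEN:
        return OmegaCode.LOWDIV, None
    try:
        value = float(token)
    except ValueError as err:
        raise ValueError(f"unknown omega token {token!r}") from err
    if value < 0 or not np.isfinite(value):
        raise ValueError(f"omega out of range: {token!r}")
    return OmegaCode.VALUE, value


M0_BRANCH = "M0"


class GenomeRateTable:
    """Genome-wide rate table: one M0 omega per gene plus per-branch records.

    Backed by two tidy DataFrames:

    ``m0``      columns gene_id, omega (float, NaN when the gene-wide value
                itself is a sentinel), code.
    ``branches`` columns gene_id, branch, dN, dS, omega, code, pos_sel.

    dN/dS may be NaN for records imported from published tables that print
    only the ratio.
    """

    def __init__(self, m0: pd.DataFrame, branches: pd.DataFrame):
        if m0["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in M0 table")
        self.m0 = m0.reset_index(drop=True)
        self.branches = branches.reset_index(drop=True)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: "list[BranchRateRecord]",
        m0_omega: "dict[str, float]",
        pos_sel: "dict[tuple[str, str], bool] | None" = None,
    ) -> "GenomeRateTable":
        pos_sel = pos_sel or {}
        rows = [
            {
                "gene_id": r.gene_id,
                "branch": r.branch,
                "dN": r.dN,
                "dS": r.dS,
                "omega": r.omega if r.code is OmegaCode.VALUE else np.nan,
                "code": r.code.value,
                "pos_sel": bool(pos_sel.get((r.gene_id, r.branch), False)),
            }
            for r in records
        ]
        m0 = pd.DataFrame(
            {
                "gene_id": list(m0_omega),
                "omega": [m0_omega[g] for g in m0_omega],
                "code": OmegaCode.VALUE.value,
            }
        )
        return cls(m0, pd.DataFrame(rows))

    def gene_records(self, gene_id: str) -> list[BranchRateRecord]:
        sub = self.branches[self.branches["gene_id"] == gene_id]
        out = []
        for row in sub.itertuples():
            code = OmegaCode(row.code)
            out.append(
                BranchRateRecord(
                    row.gene_id,
                    row.branch,
                    float(row.dN) if np.isfinite(row.dN) else np.nan,
                    float(row.dS) if np.isfinite(row.dS) else np.nan,
                    code,
                    float(row.omega) if code is OmegaCode.VALUE else None,
                )
            )
        return out

    @property
    def gene_ids(self) -> list[str]:
        return list(self.m0["gene_id"])


def read_rate_table(path, low_div_threshold: float = LOW_DIV_THRESHOLD) -> GenomeRateTable:
    """Read a TSV rate table (columns gene, branch, dN, dS, omega[, pos_sel]).

    The omega cell may be a number, ``>1`` or ``-``.  Rows whose branch is
    ``M0`` carry the gene-wide value.  Empty dN/dS cells are allowed for
    published tables printing only the ratio.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "branch": str, "omega": str},
        float_precision="round_trip",
    )
    required = {"gene", "branch", "omega"}
    if not required.issubset(df.columns):
        raise ValueError(f"rate table must have columns {sorted(required)}")
    for col in ("dN", "dS"):
        if col not in df.columns:
            df[col] = np.nan
    if ((df["dN"].fillna(0) < 0) | (df["dS"].fillna(0) < 0)).any():
        raise ValueError("negative dN or dS in rate table")
    codes, values = [], []
    for token in df["omega"].astype(str):
        code, value = parse_omega_token(token)
        codes.append(code.value)
        values.append(value if value is not None else np.nan)
    df = df.rename(columns={"gene": "gene_id"})
    df["code"] = codes
    df["omega_value"] = values
    if "pos_sel" not in df.columns:
        df["pos_sel"] = False
    else:
        df["pos_sel"] = df["pos_sel"].astype(str).str.lower().isin(("1", "true", "yes"))
    is_m0 = df["branch"] == M0_BRANCH
    m0 = df[is_m0][["gene_id", "omega_value", "code"]].rename(
        columns={"omega_value": "omega"}
    )
    branches = df[~is_m0][
        ["gene_id", "branch", "dN", "dS", "omega_value", "code", "pos_sel"]
    ].rename(columns={"omega_value": "omega"})
    logger.info(
        "read rate table %s: %d genes (M0), %d branch records", path, len(m0), len(branches)
    )
    return GenomeRateTable(m0, branches)


def write_rate_table(table: GenomeRateTable, path) -> None:
    rows = []
    for row in table.m0.itertuples():
        token = (
            str(row.omega)
            if OmegaCode(row.code) is OmegaCode.VALUE
            else {OmegaCode.GT1: GT1_TOKEN, OmegaCode.LOWDIV: LOWDIV_TOKEN}[OmegaCode(row.code)]
        )
        rows.append((row.gene_id, M0_BRANCH, "", "", token, ""))
    for row in table.branches.itertuples():
        code = OmegaCode(row.code)
        if code is OmegaCode.GT1:
            token = GT1_TOKEN
        elif code is OmegaCode.LOWDIV:
            token = LOWDIV_TOKEN
        else:
            token = str(row.omega)
        rows.append(
            (
                row.gene_id,
                row.branch,
                "" if pd.isna(row.dN) else str(row.dN),
                "" if pd.isna(row.dS) else str(row.dS),
                token,
                str(bool(row.pos_sel)),
            )
        )
    out = pd.DataFrame(rows, columns=["gene", "branch", "dN", "dS", "omega", "pos_sel"])
    out.to_csv(path, sep="\t", index=False)


def summarize_divergence(table: GenomeRateTable, q: float = 95.0):
    """(dN q-percentile, dS q-percentile, omega median) over VALUE records.

    Percentiles use linear interpolation between order statistics.  Raises
    :class:`EmptyInputError` when no numeric records exist.
    """
    if not (0 < q < 100):
        raise ValueError("q must be in (0, 100)")
    vals = table.branches[table.branches["code"] == OmegaCode.VALUE.value]
    m0_vals = table.m0[table.m0["code"] == OmegaCode.VALUE.value]["omega"].dropna()
    dn = vals["dN"].dropna()
    ds = vals["dS"].dropna()
    if m0_vals.empty and dn.empty:
        raise EmptyInputError("no VALUE records to summarize")
    dn_q = float(np.percentile(dn, q)) if len(dn) else np.nan
    ds_q = float(np.percentile(ds, q)) if len(ds) else np.nan
    omega_med = float(np.median(m0_vals)) if len(m0_vals) else np.nan
    return dn_q, ds_q, omega_med
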