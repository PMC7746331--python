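"""Reading and writing GWAS summary-statistics tables and exclusion lists.

Tables are delimited text (TSV by default, CSV accepted), one row per SNP.
Required logical columns: rsid, effect_allele, other_allele, beta, se;
optional: eaf, pvalue.  Column headers are mapped explicitly via
``column_map`` — header guessing is a configuration error waiting to
happen, so there is none.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ExclusionList, SnpAssociation
from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_FIELDS = ("eaf", "pvalue")

#: identity mapping: logical field name -> column header
DEFAULT_COLUMN_MAP = {f: f for f in REQUIRED_FIELDS + OPTIONAL_FIELDS}


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    permissive: bool = False,
) -> list[SnpAssociation]:
    """Read one study's per-SNP association summaries.

    Parameters
    ----------
    path : path-like
        Delimited text file; delimiter inferred from the extension
        (``.csv`` -> comma, anything else -> tab).
    column_map : mapping, optional
        Logical field name -> column header in the file.  Unmapped optional
        fields (eaf, pvalue) are read as missing.
    permissive : bool
        When True, rows with unparseable/missing beta or se are dropped with
        a logged count instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary table not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    for field in REQUIRED_FIELDS:
        if cmap[field] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {cmap[field]!r} (for field {field!r}) "
                f"not found; available: {list(df.columns)}"
            )

    records: list[SnpAssociation] = []
    n_dropped = 0
    for i, row in df.iterrows():
        rsid = str(row[cmap["rsid"]]).strip()
        try:
            beta = float(row[cmap["beta"]])
            se = float(row[cmap["se"]])
        except (TypeError, ValueError):
            if permissive:
                n_dropped += 1
                continue
            raise ValidationError(
                f"{path} row {i} ({rsid}): beta/se not parseable as numbers"
            )
        if np.isnan(beta) or np.isnan(se):
            if permissive:
                n_dropped += 1
                continue
            raise ValidationError(f"{path} row {i} ({rsid}): missing beta or se")
        kwargs = {}
        for opt in OPTIONAL_FIELDS:
            col = cmap.get(opt)
            if col in df.columns:
                val = row[col]
                try:
                    fval = float(val)
                except (TypeError, ValueError):
                    fval = np.nan
                kwargs[opt] = None if np.isnan(fval) else fval
        records.append(
            SnpAssociation(
                rsid=rsid,
                effect_allele=str(row[cmap["effect_allele"]]).strip(),
                other_allele=str(row[cmap["other_allele"]]).strip(),
                beta=beta,
                se=se,
                **kwargs,
            )
        )
    if n_dropped:
        log.warning("%s: dropped %d rows with missing beta/se", path, n_dropped)
    return records


def write_summary_table(records: list[SnpAssociation], path) -> None:
    path = Path(path)
    rows = [
        {
            "rsid": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path), index=False)


def read_exclusion_list(path) -> ExclusionList:
    """Read a two-column (rsid, reason) delimited text file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"exclusion list not found: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    if "rsid" not in df.columns:
        raise ConfigurationError(f"{path}: exclusion list needs an 'rsid' column")
    rsids = [str(r).strip() for r in df["rsid"]]
    reasons = {}
    if "reason" in df.columns:
        reasons = {
            rsid: str(reason)
            for rsid, reason in zip(rsids, df["reason"])
            if not pd.isna(reason)
        }
    return ExclusionList(rsids=frozenset(rsids), reasons=reasons)
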