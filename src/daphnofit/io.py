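"""Readers and writers for the tabular formats the pipeline touches.

Life histories travel as comma-separated long-form tables (one row per
observation); matrices (counts, taxonomy, metadata, distance matrices)
are tab-separated. Lines starting with ``#`` are ignored everywhere.
Result objects round-trip through TSV or JSON without loss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GrowthFit,
    LifeHistoryRecord,
    OtuTable,
    PopGrowthResult,
    ValidationError,
)

_LIFE_HISTORY_COLUMNS = ["individual_id", "treatment", "last_day", "event",
                         "obs_type", "day", "value"]


def read_life_history(path) -> list[LifeHistoryRecord]:
    """Read life-history records from a long-form CSV.

    Expected header: ``individual_id,treatment,last_day,event,obs_type,day,value``
    with one ``status`` row per individual and one ``clutch`` / ``length``
    row per observation. Returns records sorted by ``individual_id``.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(_LIFE_HISTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"life-history file lacks columns: {sorted(missing)}")
    if df.empty:
        return []
    records = []
    for ind, grp in df.groupby("individual_id", sort=True):
        treatment = float(grp["treatment"].iloc[0])
        if treatment < 0 or not np.isfinite(treatment):
            raise ValidationError(f"{ind}: unknown treatment {treatment!r}")
        last_day = int(grp["last_day"].iloc[0])
        event = bool(int(grp["event"].iloc[0]))
        clutch_rows = grp[grp["obs_type"] == "clutch"].sort_values("day")
        length_rows = grp[grp["obs_type"] == "length"].sort_values("day")
        records.append(LifeHistoryRecord(
            individual_id=str(ind),
            treatment=treatment,
            last_day=last_day,
            event=event,
            clutches=tuple(zip(clutch_rows["day"].astype(int),
                               clutch_rows["value"].astype(int))),
            lengths=tuple(zip(length_rows["day"].astype(int),
                              length_rows["value"].astype(float))),
        ))
    return records


def write_life_history(records: Sequence[LifeHistoryRecord], path) -> None:
    from .datatypes import records_to_frame

    records_to_frame(records).to_csv(path, index=False)


def read_otu_table(counts_path, taxonomy_path, meta_path) -> OtuTable:
    """Assemble an :class:`OtuTable` from three TSV files.

    ``counts_path``: samples x OTUs integer matrix, sample ids in the
    first column. ``taxonomy_path``: OTU id followed by rank columns.
    ``meta_path``: sample id followed by at least ``treatment``,
    ``clutch``, ``day``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    return OtuTable(counts, taxonomy, meta)


def write_otu_table(table: OtuTable, counts_path, taxonomy_path, meta_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.taxonomy.to_csv(taxonomy_path, sep="\t")
    table.sample_meta.to_csv(meta_path, sep="\t")


def _result_to_dict(result):
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        return {"__type__": type(result).__name__,
                **dataclasses.asdict(result)}
    if isinstance(result, pd.DataFrame):
        return {"__type__": "DataFrame",
                "data": json.loads(result.to_json(orient="split"))}
    if isinstance(result, dict):
        return {"__type__": "dict",
                "data": {k: _result_to_dict(v) for k, v in result.items()}}
    return result


_RESULT_TYPES = {"GrowthFit": GrowthFit, "PopGrowthResult": PopGrowthResult}


def _result_from_dict(payload):
    if not isinstance(payload, dict) or "__type__" not in payload:
        return payload
    kind = payload["__type__"]
    if kind == "DataFrame":
        d = payload["data"]
        return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
    if kind == "dict":
        return {k: _result_from_dict(v) for k, v in payload["data"].items()}
    cls = _RESULT_TYPES[kind]
    kwargs = {k: v for k, v in payload.items() if k != "__type__"}
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)


def write_results(result, path, format: str = "json") -> None:
    """Write a result object (dataclass, DataFrame or dict of those).

    JSON preserves full precision via ``repr`` floats; TSV is available
    for flat DataFrames. Reading back with :func:`read_results`
    reproduces the values exactly.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_result_to_dict(result), fh, indent=1)
    elif format == "tsv":
        if isinstance(result, pd.DataFrame):
            result.to_csv(path, sep="\t", float_format=None)
        elif dataclasses.is_dataclass(result) and not isinstance(result, type):
            flat = {k: [repr(v)] for k, v in dataclasses.asdict(result).items()}
            pd.DataFrame(flat).to_csv(path, sep="\t", index=False)
        else:
            raise ValidationError(f"cannot write {type(result).__name__} as TSV")
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_results(path, format: str = "json"):
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return _result_from_dict(json.load(fh))
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    raise ValidationError(f"unknown format {format!r}")
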