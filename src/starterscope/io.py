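"""Plain-text readers and writers for the pipeline's table dialects.

Community tables are TSV/CSV with the first column holding sample ids
and the header row holding taxon ids; taxon annotations live in a
sidecar TSV (taxon_id, kingdom, group). Metadata tables may carry a
``#type`` row declaring each variable categorical or continuous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityTable, DistanceMatrix
from .voc_function import VOCTable

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_annotations",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_cfu_table",
    "read_voc_table",
    "read_alkanes",
]


def _sep(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_community_table(
    path: str,
    annotations_path: str,
    relative: bool = False,
    transpose: bool = False,
) -> CommunityTable:
    """Read a sample x taxon table plus its annotation sidecar.

    ``transpose=True`` handles the taxa-as-rows dialect.
    """
    data = pd.read_csv(path, sep=_sep(path), index_col=0)
    if transpose:
        data = data.T
    annotations = read_annotations(annotations_path)
    return CommunityTable(data, annotations, relative=relative)


def write_community_table(table: CommunityTable, path: str) -> None:
    table.data.to_csv(path, sep=_sep(path), index_label="sample_id")


def read_annotations(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep(path))
    required = {"taxon_id", "kingdom", "group"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation sidecar needs columns {sorted(required)}")
    return ann.set_index("taxon_id")


def read_metadata(path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a metadata TSV; a first row with id ``#type`` types each variable.

    Without a type row, numeric columns default to continuous and the
    rest to categorical.
    """
    raw = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    types: dict[str, str] = {}
    if "#type" in raw.index:
        types = raw.loc["#type"].to_dict()
        raw = raw.drop(index="#type")
    out = {}
    for col in raw.columns:
        declared = types.get(col)
        series = raw[col]
        if declared == "continuous":
            out[col] = pd.to_numeric(series)
        elif declared == "categorical":
            out[col] = series
        else:
            try:
                out[col] = pd.to_numeric(series)
                types[col] = "continuous"
            except (ValueError, TypeError):
                out[col] = series
                types[col] = "categorical"
    return pd.DataFrame(out, index=raw.index), types


def write_metadata(metadata: pd.DataFrame, types: dict[str, str], path: str) -> None:
    typed = pd.DataFrame([types], index=["#type"])
    pd.concat([typed, metadata.astype(object)]).to_csv(
        path, sep=_sep(path), index_label="sample_id"
    )


def read_distance_matrix(path: str, metric_name: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column ids differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), metric_name)


def write_distance_matrix(d: DistanceMatrix, path: str) -> None:
    d.to_frame().to_csv(path, sep=_sep(path), index_label="id")


def read_cfu_table(path: str) -> pd.DataFrame:
    """Long-format competition CFU table.

    Needs columns pair, species_a, species_b, replicate, transfer,
    species, cfu.
    """
    df = pd.read_csv(path, sep=_sep(path))
    df["cfu"] = pd.to_numeric(df["cfu"])
    df["transfer"] = pd.to_numeric(df["transfer"]).astype(int)
    return df


def read_voc_table(path: str) -> VOCTable:
    data = pd.read_csv(path, sep=_sep(path), index_col=0)
    return VOCTable(data.astype(float))


def read_alkanes(path: str) -> dict[int, float]:
    """Alkane standards TSV with columns carbon_number, rt_min."""
    df = pd.read_csv(path, sep=_sep(path))
    return {int(c): float(rt) for c, rt in zip(df["carbon_number"], df["rt_min"])}


def read_rise_series(path: str, calib_path: str):
    """Rise TSV (tube, inoculum, replicate, time_h, pixels) + calibration."""
    from .kinetics import normalize_heights

    long = pd.read_csv(path, sep=_sep(path))
    calib = pd.read_csv(calib_path, sep=_sep(calib_path)).set_index("tube")
    series = []
    for tube, grp in long.groupby("tube", sort=True):
        grp = grp.sort_values("time_h")
        row = calib.loc[tube]
        series.append(
            normalize_heights(
                str(tube),
                str(grp["inoculum"].iloc[0]),
                int(grp["replicate"].iloc[0]),
                grp["time_h"].to_numpy(dtype=float),
                grp["pixels"].to_numpy(dtype=float),
                x0=float(row["x0"]),
                tube_height_px=float(row["th_px"]),
                tube_mm=float(row.get("tube_mm", 103.0)),
            )
        )
    return series


def read_geocoordinates(path: str):
    from .biogeography import GeoCoordinates

    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    cols = {c.lower(): c for c in df.columns}
    lat = df[cols["latitude"]].to_numpy(dtype=float)
    lon = df[cols["longitude"]].to_numpy(dtype=float)
    return GeoCoordinates(list(df.index), lat, lon)
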