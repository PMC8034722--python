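"""Privacy-protected exposure analysis from GPS traces.

Point features (e.g. fast-food outlets) are buffered into closed discs of
radius ``r``; each individual's commute trace, a planar polyline, is
intersected with the buffers; the number of *distinct* buffers touched is
that individual's exposure count. Repeated passes through one buffer count
once, and boundary contact counts as exposed (the buffer is a closed
region). The exposure column is then joined with the phenotype table inside
each node and the outcome model (e.g. BMI on exposure plus confounders) is
fitted with the federated GLM — traces, coordinates and per-individual
exposure vectors never leave a node.

Coordinates are planar Cartesian metres; project geodetic data upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

from .disclosure import DisclosureBlocked
from .federation import ClientSession, GuardContext, server_op
from .glm import GLMFit, GLMSpec, glm_fit_federated


class GeoError(Exception):
    pass


@dataclass
class OutletSet:
    """Point features: unique ids plus planar coordinates in metres."""

    ids: list[str]
    coords: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise GeoError("outlet coordinates must be an (n, 2) array")
        if len(self.ids) != len(self.coords):
            raise GeoError("outlet ids and coordinates differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise GeoError("outlet ids must be unique")
        if not np.isfinite(self.coords).all():
            raise GeoError("outlet coordinates must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OutletSet":
        return cls(ids=[str(i) for i in df["id"]], coords=df[["x", "y"]].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]})


@dataclass
class TraceSet:
    """Per-individual polylines (>= 2 vertices each), metres."""

    traces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned = {}
        for tid, pts in self.traces.items():
            pts = np.asarray(pts, float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
                raise GeoError(f"trace {tid!r} must have >= 2 planar vertices")
            cleaned[str(tid)] = pts
        self.traces = cleaned

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraceSet":
        """Long format: columns id, seq, x, y; vertices ordered by seq."""
        traces = {}
        for tid, group in df.sort_values("seq").groupby("id", sort=True):
            traces[str(tid)] = group[["x", "y"]].to_numpy(float)
        return cls(traces)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for tid, pts in self.traces.items():
            for seq, (x, y) in enumerate(pts):
                records.append((tid, seq, x, y))
        return pd.DataFrame(records, columns=["id", "seq", "x", "y"])

    def translate(self, dx: float, dy: float) -> "TraceSet":
        return TraceSet({tid: pts + np.array([dx, dy]) for tid, pts in self.traces.items()})


@dataclass
class BufferSet:
    """Closed regular-polygon circle approximations around each outlet."""

    ids: list[str]
    polygons: list[Polygon]
    radius: float
    segments: int

    def polygon_for(self, outlet_id: str) -> Polygon:
        return self.polygons[self.ids.index(outlet_id)]


def buffer_points(outlets: OutletSet, radius: float, segments: int = 64) -> BufferSet:
    """Buffer each outlet into a ``segments``-gon inscribed in the circle of
    ``radius`` metres, vertices at angles 2*pi*k/segments."""
    if radius <= 0:
        raise GeoError("buffer radius must be positive")
    if segments < 8:
        raise GeoError("circle approximation needs at least 8 segments")
    angles = 2.0 * np.pi * np.arange(segments) / segments
    ring = np.column_stack([np.cos(angles), np.sin(angles)]) * radius
    polygons = [Polygon(ring + centre) for centre in outlets.coords]
    return BufferSet(list(outlets.ids), polygons, float(radius), int(segments))


def trace_exposure_counts(traces: TraceSet, buffers: BufferSet) -> pd.Series:
    """Exposure count per individual: number of distinct buffers the trace
    intersects (boundary contact included). Returns a Series indexed by
    individual id, named ``exposure_count``."""
    tree = STRtree(buffers.polygons)
    counts = {}
    for tid, pts in traces.traces.items():
        line = LineString(pts)
        hits = tree.query(line, predicate="intersects")
        counts[tid] = int(len(np.unique(hits)))
    return pd.Series(counts, name="exposure_count").rename_axis("id")


# ---------------------------------------------------------------------------
# Server-side pipeline step

@server_op("geo_prepare")
def _op_geo_prepare(
    node,
    traces_symbol: str,
    outlets_symbol: str,
    pheno_symbol: str,
    radius: float,
    segments: int = 64,
    out_symbol: str = "geo_model",
):
    """Buffer -> intersect -> count -> join, entirely inside the node.

    Binds the joined phenotype+exposure table to ``out_symbol`` and
    acknowledges with dimensions only. An id mismatch between traces and
    phenotypes is reported as counts, never as ids.
    """
    traces_df = node.get_dataset(traces_symbol)
    outlets_df = node.get_dataset(outlets_symbol)
    pheno = node.get_dataset(pheno_symbol)
    for name, df in ((traces_symbol, traces_df), (outlets_symbol, outlets_df), (pheno_symbol, pheno)):
        if not isinstance(df, pd.DataFrame):
            raise GeoError(f"symbol {name!r} is not a tabular dataset")
    if "id" not in pheno.columns:
        raise GeoError(f"phenotype table {pheno_symbol!r} lacks an 'id' column")

    traces = TraceSet.from_frame(traces_df)
    outlets = OutletSet.from_frame(outlets_df)
    exposure = trace_exposure_counts(traces, buffer_points(outlets, radius, segments))

    pheno_ids = set(str(i) for i in pheno["id"])
    trace_ids = set(exposure.index)
    if pheno_ids != trace_ids:
        raise GeoError(
            "id mismatch between traces and phenotypes: "
            f"{len(trace_ids - pheno_ids)} trace id(s) without phenotype, "
            f"{len(pheno_ids - trace_ids)} phenotype id(s) without trace"
        )
    joined = pheno.copy()
    joined["id"] = joined["id"].astype(str)
    joined = joined.merge(exposure.reset_index(), on="id", how="inner")

    if len(joined) < node.disclosure.min_subset_size and node.disclosure.mode == "full":
        raise DisclosureBlocked(
            [
                f"subset filter: joined table has {len(joined)} row(s), below "
                f"the minimum subset size of {node.disclosure.min_subset_size}"
            ]
        )
    node.environment[out_symbol] = joined
    node._cache.clear()
    payload = {"symbol": out_symbol, "rows": int(len(joined)), "cols": int(joined.shape[1])}
    return payload, GuardContext(n_obs=int(len(joined)))


# ---------------------------------------------------------------------------
# Client-side pipeline

def geo_association_pipeline(
    session: ClientSession,
    radius: float,
    model: GLMSpec,
    traces_symbol: str = "traces",
    outlets_symbol: str = "outlets",
    pheno_symbol: str = "pheno",
    segments: int = 64,
) -> GLMFit:
    """Full exposure workflow: per node buffer/intersect/count/join, then a
    federated GLM of the outcome on ``exposure_count`` plus covariates.
    Only GLM aggregates leave the nodes."""
    responses = session.broadcast(
        "geo_prepare",
        {
            "traces_symbol": traces_symbol,
            "outlets_symbol": outlets_symbol,
            "pheno_symbol": pheno_symbol,
            "radius": radius,
            "segments": segments,
            "out_symbol": "geo_model",
        },
    )
    failed = [r for r in responses if not r.ok]
    if failed:
        raise GeoError(
            f"exposure preparation failed on node {failed[0].node_name!r}: "
            + "; ".join(failed[0].messages)
        )
    return glm_fit_federated(session, model, data_symbol="geo_model")
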