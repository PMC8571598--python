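"""Readers and writers for the plain-text interchange formats.

Networks come in as GeoJSON LineString/MultiLineString features or a CSV
edge list (``edge_id,x,y,vertex_order``); detectors as a wide CSV with one
effort column per occasion; detection histories and genotypes as long and
wide (GenAlEx-style two-columns-per-locus) CSVs respectively.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .genotypes import ConsensusGenotype, IndividualAssignment
from .history import DetectionHistory
from .network import DetectorArray, LinearNetwork, StateSpace, build_network, \
    snap_detectors

__all__ = [
    "read_network_geojson",
    "write_network_geojson",
    "read_network_csv",
    "read_detectors_csv",
    "write_detectors_csv",
    "write_state_space_csv",
    "read_history_csv",
    "write_history_csv",
    "read_genotypes_csv",
    "write_genotypes_csv",
]


def read_network_geojson(path, snap_tolerance: float = 1.0) -> LinearNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    polylines = []
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for f in feats:
        geom = f.get("geometry", f)
        if geom["type"] == "LineString":
            polylines.append(np.asarray(geom["coordinates"], float))
        elif geom["type"] == "MultiLineString":
            polylines.extend(np.asarray(c, float) for c in geom["coordinates"])
        else:
            raise ValueError(f"unsupported geometry type {geom['type']}")
    return build_network(polylines, snap_tolerance=snap_tolerance)


def write_network_geojson(net: LinearNetwork, path) -> None:
    feats = [{
        "type": "Feature",
        "properties": {"edge_id": e, "length_m": float(net.lengths[e])},
        "geometry": {"type": "LineString",
                     "coordinates": [list(map(float, c))
                                     for c in net.geometries[e].coords]},
    } for e in range(net.n_edges)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_network_csv(path, snap_tolerance: float = 1.0) -> LinearNetwork:
    """Edge-list CSV with columns edge_id, x, y, vertex_order."""
    df = pd.read_csv(path)
    polylines = [
        g.sort_values("vertex_order")[["x", "y"]].to_numpy(float)
        for _, g in df.groupby("edge_id", sort=True)
    ]
    return build_network(polylines, snap_tolerance=snap_tolerance)


def read_detectors_csv(path, net: LinearNetwork,
                       max_displacement: float = np.inf) -> DetectorArray:
    """Wide CSV: detector_id, x, y, effort_1 .. effort_O."""
    df = pd.read_csv(path)
    eff_cols = [c for c in df.columns if c.startswith("effort_")]
    if not eff_cols:
        raise ValueError("no effort_<occasion> columns found")
    eff_cols.sort(key=lambda c: int(c.split("_")[1]))
    return snap_detectors(
        net, df[["x", "y"]].to_numpy(float), df[eff_cols].to_numpy(float),
        ids=[str(i) for i in df["detector_id"]],
        max_displacement=max_displacement)


def write_detectors_csv(det: DetectorArray, net: LinearNetwork, path) -> None:
    xy = np.array([net.to_xy(p) for p in det.positions])
    df = pd.DataFrame({"detector_id": det.ids, "x": xy[:, 0], "y": xy[:, 1]})
    for o in range(det.n_occasions):
        df[f"effort_{o + 1}"] = det.effort[:, o]
    df.to_csv(path, index=False)


def write_state_space_csv(space: StateSpace, path) -> None:
    df = pd.DataFrame({
        "point_id": np.arange(space.n_points),
        "x": space.xy[:, 0],
        "y": space.xy[:, 1],
        "cell_len_m": space.cell_lengths,
    })
    for name, vals in space.covariates.items():
        col = {"latitude": "latitude", "dist_release": "dist_release_m"}.get(name, name)
        df[col] = vals
    df.to_csv(path, index=False)


def write_history_csv(history: DetectionHistory, det: DetectorArray,
                      path, sex_path=None) -> None:
    """Long CSV individual,latrine,occasion,count (nonzero cells only)."""
    rows = []
    for i, k, o in zip(*np.nonzero(history.counts)):
        rows.append({"individual": history.individual_ids[i],
                     "latrine": det.ids[k], "occasion": int(o) + 1,
                     "count": int(history.counts[i, k, o])})
    pd.DataFrame(rows, columns=["individual", "latrine", "occasion", "count"]
                 ).to_csv(path, index=False)
    if sex_path is not None:
        pd.DataFrame({"individual": history.individual_ids,
                      "sex": history.sexes}).to_csv(sex_path, index=False)


def read_history_csv(path, det: DetectorArray, n_occasions: int,
                     sex_path=None) -> DetectionHistory:
    df = pd.read_csv(path)
    ids = sorted(df["individual"].astype(str).unique())
    counts = np.zeros((len(ids), det.n_detectors, n_occasions), int)
    idx = {v: i for i, v in enumerate(ids)}
    for _, r in df.iterrows():
        counts[idx[str(r["individual"])], det.index_of(str(r["latrine"])),
               int(r["occasion"]) - 1] += int(r["count"])
    sexes = ["unknown"] * len(ids)
    if sex_path is not None:
        sx = pd.read_csv(sex_path)
        m = dict(zip(sx["individual"].astype(str), sx["sex"]))
        sexes = [m.get(i, "unknown") for i in ids]
    return DetectionHistory(counts=counts, sexes=sexes, individual_ids=ids)


def write_genotypes_csv(consensus: list[ConsensusGenotype], path) -> None:
    """Wide GenAlEx-style CSV: two allele columns per locus, blank = missing."""
    loci = sorted({l for c in consensus for l in c.genotype})
    rows = []
    for c in consensus:
        row = {"sample_id": c.sample_id, "latrine_id": c.latrine_id,
               "occasion": c.occasion, "sex": c.sex}
        for l in loci:
            pair = c.genotype.get(l)
            row[f"{l}_1"] = pair[0] if pair else ""
            row[f"{l}_2"] = pair[1] if pair else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotypes_csv(path) -> list[ConsensusGenotype]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    loci = sorted({c[:-2] for c in df.columns if c.endswith("_1")})
    out = []
    for _, r in df.iterrows():
        geno = {}
        for l in loci:
            a1, a2 = r[f"{l}_1"], r[f"{l}_2"]
            geno[l] = tuple(sorted((a1, a2))) if a1 and a2 else None
        out.append(ConsensusGenotype(
            sample_id=r["sample_id"], genotype=geno,
            sex=r.get("sex", "unknown") or "unknown",
            latrine_id=r.get("latrine_id") or None,
            occasion=int(r["occasion"]) if r.get("occasion") else None))
    return out
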