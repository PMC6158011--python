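"""Readers and writers for skeleton and volume formats.

Supported formats
-----------------
* NML — the webKnossos XML skeleton dialect: ``<things>`` containing
  ``<parameters><scale .../></parameters>``, per-tree ``<thing>`` (or
  ``<tree>``) elements with ``<nodes>``/``<edges>``, plus ``<comments>`` and
  ``<branchpoints>``.  Node coordinates are kept in stored voxel units;
  :func:`to_physical` converts once to nanometres using the scale element.
* SWC — the standard 7-column morphology format.  Positions are interpreted
  as micrometres (standard SWC practice) and converted to nm.
* Control-point CSV — corresponding LM/EM landmark pairs.
* Multi-page TIFF — single-channel volume stacks.

The ``<scale>`` element is required in NML input: there is no silent default
voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

from .skeletons import DatasetGeometry, Skeleton

CP_SOURCES = ("blood_vessel", "varicosity", "branchpoint", "other")
CP_COLUMNS = ["cp_id", "lm_x", "lm_y", "lm_z", "em_x", "em_y", "em_z", "source"]


# ---------------------------------------------------------------------------
# NML
# ---------------------------------------------------------------------------

@dataclass
class NMLDocument:
    """Parsed webKnossos annotation; tree positions in stored voxel units."""

    experiment: str
    scale: np.ndarray  # nm / voxel
    trees: list[Skeleton] = field(default_factory=list)

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=float)
        if self.scale.shape != (3,) or np.any(self.scale <= 0):
            raise ValueError("scale must be a positive 3-vector")
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tree ids")


class NMLParseError(ValueError):
    pass


def read_nml(path) -> NMLDocument:
    """Parse an NML file. Raises :class:`NMLParseError` on malformed input."""
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise NMLParseError(f"malformed NML XML: {exc}") from exc
    scale_el = root.find("parameters/scale")
    if scale_el is None:
        scale_el = root.find(".//scale")
    if scale_el is None:
        raise NMLParseError("NML file has no <scale> element; voxel size "
                            "must be declared explicitly")
    scale = np.array([float(scale_el.get(k)) for k in ("x", "y", "z")])
    exp_el = root.find("parameters/experiment")
    experiment = exp_el.get("name") if exp_el is not None else ""

    comments: dict[int, str] = {}
    for c in root.iterfind("comments/comment"):
        comments[int(c.get("node"))] = c.get("content", "")
    branchpoints = {int(b.get("id"))
                    for b in root.iterfind("branchpoints/branchpoint")}

    trees = []
    tree_elements = list(root.iterfind("thing")) + list(root.iterfind("tree"))
    for t in tree_elements:
        node_ids, positions, radii = [], [], []
        for n in t.iterfind("nodes/node"):
            node_ids.append(int(n.get("id")))
            positions.append([float(n.get(k)) for k in ("x", "y", "z")])
            radii.append(float(n.get("radius", "nan")))
        edges = [(int(e.get("source")), int(e.get("target")))
                 for e in t.iterfind("edges/edge")]
        annotations: dict[int, set] = {}
        for nid in node_ids:
            tags = set()
            if nid in comments:
                text = comments[nid]
                tags.add(f"comment:{text}")
                # recognized annotation keywords travel as bare tags too
                for kw in ("varicosity", "branchpoint", "seed"):
                    if kw in text.lower():
                        tags.add(kw)
            if nid in branchpoints:
                tags.add("branchpoint")
            if tags:
                annotations[nid] = tags
        trees.append(Skeleton(
            tree_id=int(t.get("id")), name=t.get("name", ""),
            node_ids=np.array(node_ids, dtype=np.int64),
            positions=np.array(positions, dtype=float).reshape(-1, 3),
            edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
            radii=np.array(radii) if radii else None,
            annotations=annotations))
    return NMLDocument(experiment=experiment, scale=scale, trees=trees)


def to_physical(doc: NMLDocument) -> list[Skeleton]:
    """Convert stored voxel positions to nm: ``position_nm = voxel * scale``."""
    return [t.transformed(lambda p: p * doc.scale) for t in doc.trees]


def write_nml(skeletons, geometry: DatasetGeometry, path, experiment="",
              positions_are_physical=False):
    """Write skeletons as NML.

    If ``positions_are_physical`` the nm positions are divided by the voxel
    size before writing (NML stores voxel units).
    """
    root = etree.Element("things")
    params = etree.SubElement(root, "parameters")
    etree.SubElement(params, "experiment", name=experiment)
    sx, sy, sz = geometry.voxel_size
    etree.SubElement(params, "scale", x=repr(float(sx)), y=repr(float(sy)),
                     z=repr(float(sz)))
    comments_el = etree.Element("comments")
    branch_el = etree.Element("branchpoints")
    for s in skeletons:
        thing = etree.SubElement(root, "thing", id=str(s.tree_id),
                                 name=s.name or "")
        nodes_el = etree.SubElement(thing, "nodes")
        pos = s.positions / geometry.voxel_size if positions_are_physical \
            else s.positions
        for k, nid in enumerate(s.node_ids.tolist()):
            attrs = {"id": str(nid), "x": repr(float(pos[k, 0])),
                     "y": repr(float(pos[k, 1])), "z": repr(float(pos[k, 2]))}
            if s.radii is not None and np.isfinite(s.radii[k]):
                attrs["radius"] = repr(float(s.radii[k]))
            etree.SubElement(nodes_el, "node", **attrs)
        edges_el = etree.SubElement(thing, "edges")
        for a, b in s.edges.tolist():
            etree.SubElement(edges_el, "edge", source=str(a), target=str(b))
        for nid, tags in sorted(s.annotations.items()):
            text = next((t[len("comment:"):] for t in sorted(tags)
                         if t.startswith("comment:")), None)
            bare = sorted(t for t in tags if not t.startswith("comment:"))
            content = text if text is not None else " ".join(bare)
            if content:
                etree.SubElement(comments_el, "comment", node=str(nid),
                                 content=content)
            if "branchpoint" in tags:
                etree.SubElement(branch_el, "branchpoint", id=str(nid))
    root.append(branch_el)
    root.append(comments_el)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# control points
# ---------------------------------------------------------------------------

@dataclass
class ControlPointTable:
    """Corresponding LM/EM landmark pairs, positions in nm."""

    cp_ids: np.ndarray
    lm: np.ndarray  # (n, 3) nm
    em: np.ndarray  # (n, 3) nm
    source: np.ndarray  # object array of tags

    def __post_init__(self):
        self.cp_ids = np.asarray(self.cp_ids)
        self.lm = np.asarray(self.lm, dtype=float).reshape(-1, 3)
        self.em = np.asarray(self.em, dtype=float).reshape(-1, 3)
        self.source = np.asarray(self.source, dtype=object)
        if len(set(self.cp_ids.tolist())) != len(self.cp_ids):
            raise ValueError("duplicate cp_id")
        if not (np.all(np.isfinite(self.lm)) and np.all(np.isfinite(self.em))):
            raise ValueError("non-finite control point position")

    def __len__(self):
        return len(self.cp_ids)

    def subset(self, indices) -> "ControlPointTable":
        idx = np.asarray(indices)
        return ControlPointTable(self.cp_ids[idx], self.lm[idx],
                                 self.em[idx], self.source[idx])

    @classmethod
    def from_arrays(cls, lm, em, source="other", cp_ids=None):
        lm = np.asarray(lm, dtype=float).reshape(-1, 3)
        n = len(lm)
        if cp_ids is None:
            cp_ids = np.arange(n)
        src = np.full(n, source, dtype=object) if isinstance(source, str) \
            else np.asarray(source, dtype=object)
        return cls(cp_ids, lm, em, src)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cp_id": self.cp_ids,
            "lm_x": self.lm[:, 0], "lm_y": self.lm[:, 1], "lm_z": self.lm[:, 2],
            "em_x": self.em[:, 0], "em_y": self.em[:, 1], "em_z": self.em[:, 2],
            "source": self.source})

    def write_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def read_control_points(path_csv, units="nm",
                        geometry_lm: DatasetGeometry | None = None,
                        geometry_em: DatasetGeometry | None = None,
                        column_map: dict | None = None) -> ControlPointTable:
    """Read a control-point CSV.

    ``units`` is "nm" (default) or "voxel"; voxel input requires both
    geometries.  ``column_map`` renames nonstandard columns onto the expected
    schema, so figure source-data tables with other headers can be loaded
    without a hard-coded layout.
    """
    df = pd.read_csv(path_csv)
    if column_map:
        df = df.rename(columns=column_map)
    if len(df) == 0:
        return ControlPointTable(np.empty(0), np.empty((0, 3)),
                                 np.empty((0, 3)), np.empty(0, dtype=object))
    missing = [c for c in CP_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"control point table missing columns: {missing}")
    lm = df[["lm_x", "lm_y", "lm_z"]].to_numpy(dtype=float)
    em = df[["em_x", "em_y", "em_z"]].to_numpy(dtype=float)
    if units == "voxel":
        if geometry_lm is None or geometry_em is None:
            raise ValueError("voxel units require LM and EM geometries")
        lm = lm * geometry_lm.voxel_size
        em = em * geometry_em.voxel_size
    elif units != "nm":
        raise ValueError(f"unknown units {units!r}")
    source = (df["source"].astype(str).to_numpy(dtype=object)
              if "source" in df.columns else np.full(len(df), "other", object))
    return ControlPointTable(df["cp_id"].to_numpy(), lm, em, source)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeStack:
    """Single-channel 3D volume (planes, y, x) with grid metadata."""

    data: np.ndarray
    geometry: DatasetGeometry
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) == 0:
            raise ValueError("volume must be a non-empty 3D array")


def read_tiff_stack(path, geometry: DatasetGeometry | None = None,
                    channel="") -> VolumeStack:
    """Read a single-channel multi-page TIFF as (planes, y, x)."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected single-channel stack, got shape "
                         f"{data.shape}")
    if data.dtype.kind not in "uif":
        raise ValueError(f"unsupported TIFF bit depth / dtype: {data.dtype}")
    if geometry is None:
        geometry = DatasetGeometry(np.ones(3), frame_label="LM")
    return VolumeStack(data=data, geometry=geometry, channel=channel)


def write_tiff_stack(stack: VolumeStack, path):
    tifffile.imwrite(str(path), stack.data)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path) -> list[Skeleton]:
    """Read SWC (positions µm -> nm). Each connected component is one tree.

    A standard SWC file holds one tree; the 7th column links each node to its
    parent (-1 for a root).  Orphan parent ids raise a structural error.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"SWC row with {len(parts)} columns")
            rows.append((int(parts[0]), float(parts[2]), float(parts[3]),
                         float(parts[4]), float(parts[5]), int(parts[6])))
    if not rows:
        return []
    ids = {r[0] for r in rows}
    node_ids = np.array([r[0] for r in rows], dtype=np.int64)
    positions = np.array([[r[1], r[2], r[3]] for r in rows]) * 1000.0
    radii = np.array([r[4] for r in rows]) * 1000.0
    edges = []
    for r in rows:
        parent = r[5]
        if parent == -1:
            continue
        if parent not in ids:
            raise ValueError(f"SWC parent id {parent} not defined")
        edges.append((parent, r[0]))
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    # split into connected components (one Skeleton per tree)
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(node_ids.tolist())
    g.add_edges_from(edges.tolist())
    trees = []
    id_to_row = {int(i): k for k, i in enumerate(node_ids)}
    for tid, comp in enumerate(nx.connected_components(g), start=1):
        idx = [id_to_row[i] for i in sorted(comp)]
        comp_edges = edges[[k for k, (a, b) in enumerate(edges.tolist())
                            if a in comp]]
        trees.append(Skeleton(tid, node_ids[idx], positions[idx], comp_edges,
                              radii[idx]))
    return trees


def write_swc(skeleton: Skeleton, path):
    """Write one tree as SWC (nm -> µm), rooted at its first node."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(skeleton.node_ids.tolist())
    g.add_edges_from(skeleton.edges.tolist())
    root = int(skeleton.node_ids[0])
    parent = {root: -1}
    for a, b in nx.bfs_edges(g, root):
        parent[b] = a
    with open(path, "w") as fh:
        fh.write("# generated by axonmatch\n")
        for nid in skeleton.node_ids.tolist():
            p = skeleton.positions_of(nid)[0] / 1000.0
            r = 1.0
            if skeleton.radii is not None:
                rr = skeleton.radii[skeleton.index_of(nid)]
                if np.isfinite(rr):
                    r = rr / 1000.0
            fh.write(f"{nid} 0 {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r:.6f} "
                     f"{parent[nid]}\n")


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(payload: dict, path, config: dict | None = None,
                 seed=None):
    """Write a JSON result report, embedding the resolved config and seed."""
    doc = {"config": _jsonify(config or {}), "seed": seed,
           "results": _jsonify(payload)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc
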