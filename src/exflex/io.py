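"""Plain-text interchange: two-column TSV spectra with YAML sidecars,
multi-model PDB / XYZ trajectories, and series manifests.

Group labels travel in the PDB chain ID (ligand -> chain P, receptor ->
chain A, crosslink -> chain X) and can be overridden by a sidecar group-map
YAML for files produced elsewhere.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .lineshape import Spectrum, TitrationSeries
from .trajflex import ConformerTrajectory, DEFAULT_FRAME_INTERVAL_PS

GROUP_TO_CHAIN = {"ligand": "P", "receptor": "A", "crosslink": "X"}
CHAIN_TO_GROUP = {v: k for k, v in GROUP_TO_CHAIN.items()}


# ---------------------------------------------------------------------------
# Spectra


def write_spectrum_tsv(spec: Spectrum, path, meta: dict | None = None) -> None:
    """Two-column TSV (frequency_Hz, intensity) with '# ' YAML header lines."""
    path = Path(path)
    lines = []
    if meta:
        for ln in yaml.safe_dump(_plain(meta), sort_keys=False).rstrip().splitlines():
            lines.append(f"# {ln}")
    lines.append("# frequency_Hz\tintensity")
    for x, y in zip(spec.axis, spec.intensity):
        lines.append(f"{x:.12g}\t{y:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_tsv(path) -> tuple[Spectrum, dict]:
    path = Path(path)
    header, data = [], []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            header.append(line[1:].strip())
        elif line.strip():
            a, b = line.split("\t")
            data.append((float(a), float(b)))
    meta_text = "\n".join(h for h in header if not h.startswith("frequency_Hz"))
    meta = yaml.safe_load(meta_text) if meta_text.strip() else {}
    arr = np.asarray(data)
    return Spectrum(axis=arr[:, 0], intensity=arr[:, 1]), (meta or {})


def write_series(series: TitrationSeries, outdir, stem: str = "point") -> Path:
    """Write one TSV per titration point plus a manifest YAML; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    points = []
    for i, (spec, pb) in enumerate(zip(series.spectra, series.p_b)):
        fname = f"{stem}_{i:02d}.tsv"
        meta = {"p_b": float(pb)}
        if series.receptor_site_totals is not None:
            meta["receptor_sites_total_M"] = float(series.receptor_site_totals[i])
        write_spectrum_tsv(spec, outdir / fname, meta)
        points.append(dict(file=fname, **meta))
    manifest = {
        "ligand": series.name,
        "ligand_total_M": None if series.ligand_total is None else float(series.ligand_total),
        "points": points,
    }
    mpath = outdir / "series.yaml"
    mpath.write_text(yaml.safe_dump(_plain(manifest), sort_keys=False))
    return mpath


def read_series(manifest_path) -> TitrationSeries:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    spectra, p_b, conc = [], [], []
    for pt in manifest["points"]:
        spec, meta = read_spectrum_tsv(manifest_path.parent / pt["file"])
        spectra.append(spec)
        p_b.append(pt.get("p_b", meta.get("p_b")))
        conc.append(pt.get("receptor_sites_total_M", meta.get("receptor_sites_total_M", np.nan)))
    if any(v is None for v in p_b):
        raise ValueError("every titration point needs a p_b (manifest or TSV header)")
    return TitrationSeries(
        spectra=spectra,
        p_b=np.asarray(p_b, dtype=float),
        ligand_total=manifest.get("ligand_total_M"),
        receptor_site_totals=np.asarray(conc, dtype=float),
        name=manifest.get("ligand"),
        meta={"manifest": str(manifest_path)},
    )


# ---------------------------------------------------------------------------
# Trajectories


def _template_atoms(traj: ConformerTrajectory) -> struc.AtomArray:
    n = traj.n_atoms
    atoms = struc.AtomArray(n)
    res_id = np.zeros(n, dtype=int)
    rid = 0
    prev_key = None
    for i in range(n):
        name = str(traj.atom_names[i])
        group = str(traj.atom_groups[i])
        # new residue at each N (ligand), each CA (receptor trace), or group change
        if group != prev_key or (group == "receptor") or (group == "ligand" and name == "N"):
            rid += 1
        res_id[i] = rid
        prev_key = group
    atoms.res_id = res_id
    atoms.atom_name = np.array([str(x) for x in traj.atom_names])
    atoms.chain_id = np.array([GROUP_TO_CHAIN[str(g)] for g in traj.atom_groups])
    atoms.res_name = np.array(
        ["LNK" if g == "crosslink" else "GLY" for g in traj.atom_groups]
    )
    atoms.element = np.array([(str(x)[0] if str(x) else "C") for x in traj.atom_names])
    atoms.hetero = np.array([g == "crosslink" for g in traj.atom_groups])
    return atoms


def write_pdb(traj: ConformerTrajectory, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL), one model per frame."""
    stack = struc.from_template(_template_atoms(traj), traj.coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, group_map_yaml=None, frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS) -> ConformerTrajectory:
    """Read a multi-model PDB; model order = time order.

    Groups come from the chain ID (P/A/X = ligand/receptor/crosslink) unless
    a sidecar YAML provides ``chain_groups`` (chain id -> group) and/or
    ``atom_groups`` (explicit per-atom list).
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    chain_map = dict(CHAIN_TO_GROUP)
    atom_groups = None
    if group_map_yaml is not None:
        side = yaml.safe_load(Path(group_map_yaml).read_text()) or {}
        chain_map.update(side.get("chain_groups", {}))
        if "atom_groups" in side:
            atom_groups = np.asarray(side["atom_groups"], dtype=object)
    if atom_groups is None:
        unknown = sorted(set(stack.chain_id) - set(chain_map))
        if unknown:
            raise ValueError(
                f"chains {unknown} have no group mapping; provide a group-map YAML"
            )
        atom_groups = np.array([chain_map[c] for c in stack.chain_id], dtype=object)
    return ConformerTrajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name, dtype=object),
        atom_groups=atom_groups,
        frame_interval_ps=frame_interval_ps,
    )


def write_xyz(traj: ConformerTrajectory, path) -> None:
    """Concatenated-frame XYZ (atom name, x, y, z); group labels go in a sidecar."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for name, (x, y, z) in zip(traj.atom_names, traj.coords[f]):
                fh.write(f"{name} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz(path, group_map_yaml, frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS) -> ConformerTrajectory:
    """Read concatenated XYZ; requires a group-map YAML with ``atom_groups``."""
    lines = Path(path).read_text().splitlines()
    frames, names = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        if names is None:
            names = [ln.split()[0] for ln in block]
        i += 2 + n
    side = yaml.safe_load(Path(group_map_yaml).read_text())
    return ConformerTrajectory(
        coords=np.asarray(frames, dtype=float),
        atom_names=np.asarray(names, dtype=object),
        atom_groups=np.asarray(side["atom_groups"], dtype=object),
        frame_interval_ps=frame_interval_ps,
    )


def write_ground_truth(obj: dict, path) -> None:
    """Sidecar ground-truth YAML (scenario parameters, true rates, populations)."""
    Path(path).write_text(yaml.safe_dump(_plain(obj), sort_keys=False))


def read_ground_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively convert numpy scalars/arrays and dataclass-likes to YAML-safe types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _plain({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    return obj
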