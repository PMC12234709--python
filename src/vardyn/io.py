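"""Readers and writers for the pipeline's standard file formats.

Trajectories travel as multi-model PDB (MODEL/ENDMDL blocks, parsed with
biotite); evidence, features, labels and predictions as CSV/TSV; scaling
parameters, reports and run manifests as JSON. A feature workbook reader
supports a deposited-data layout with a features sheet and a separate labels
file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from ._elements import element_from_atom_name
from .labeling import CLINVAR_VALUES, EvidenceRecord
from .trajfeatures import FEATURE_NAMES, AtomRecord, FeatureVector, Trajectory

_BACKBONE_NAME_TO_ROLE = {"N": "N", "CA": "CA", "C": "C", "O": "O", "H": "H"}


def _role_for(atom_name: str) -> str:
    name = atom_name.strip()
    if name in _BACKBONE_NAME_TO_ROLE:
        return _BACKBONE_NAME_TO_ROLE[name]
    return "sidechain"


def read_multimodel_pdb(path: str | Path, frame_interval_ps: float = 10.0) -> Trajectory:
    """Parse MODEL/ENDMDL blocks into a Trajectory.

    Single-model files become one-frame trajectories. Atom masses and van der
    Waals radii come from the embedded element table; a missing element
    column is inferred from the atom name with a warning.
    """
    path = Path(path)
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # inconsistent atom counts across models
        raise ValueError(
            f"malformed multi-model PDB {path.name}: inconsistent or truncated "
            f"model (of {n_models} MODEL blocks): {exc}"
        ) from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    topology = []
    for i in range(stack.array_length()):
        element = str(first.element[i]).strip().upper()
        name = str(first.atom_name[i])
        if not element:
            element = element_from_atom_name(name)
            warnings.warn(
                f"missing element for atom {name}; inferred {element}", stacklevel=2
            )
        topology.append(
            AtomRecord(
                serial=i + 1,
                name=name,
                element=element,
                residue_index=int(first.res_id[i]),
                residue_name=str(first.res_name[i]),
                backbone_role=_role_for(name),
            )
        )
    return Trajectory(
        topology=topology,
        frames=np.asarray(stack.coord, float),
        frame_interval_ps=frame_interval_ps,
    )


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB."""
    n = trajectory.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = trajectory.frames[0].astype(np.float32)
    arr.atom_name = np.array([a.name for a in trajectory.topology])
    arr.element = np.array([a.element for a in trajectory.topology])
    arr.res_id = np.array([a.residue_index for a in trajectory.topology])
    arr.res_name = np.array([a.residue_name for a in trajectory.topology])
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * trajectory.n_frames)
    stack.coord = trajectory.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(Path(path))


EVIDENCE_COLUMNS = (
    "variant",
    "clinvar",
    "gnomad_homozygotes",
    "gnomad_af",
    "hgmd_dm",
    "clinical_panel",
)


def read_evidence_csv(path: str | Path, sep: str | None = None) -> list[EvidenceRecord]:
    """Read and validate an evidence table (CSV or TSV by extension)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing required columns: {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"evidence table {path.name} has no data rows", stacklevel=2)
        return []
    bad = set(df["clinvar"].dropna()) - set(CLINVAR_VALUES)
    if bad:
        raise ValueError(
            f"unknown clinvar values {sorted(bad)}; accepted: {list(CLINVAR_VALUES)}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(
            EvidenceRecord(
                variant=str(row["variant"]),
                clinvar=(
                    "absent" if pd.isna(row["clinvar"]) else str(row["clinvar"])
                ),
                gnomad_homozygotes=int(row["gnomad_homozygotes"] or 0),
                gnomad_af=(
                    None if pd.isna(row["gnomad_af"]) else float(row["gnomad_af"])
                ),
                hgmd_dm=bool(row["hgmd_dm"]),
                clinical_panel=str(row["clinical_panel"]),
            )
        )
    return records


def write_feature_csv(
    rows: dict[str, FeatureVector] | pd.DataFrame, path: str | Path
) -> None:
    """Per-variant feature CSV: variant id, the ten features, window bounds."""
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, index=False)
        return
    records = []
    for variant, fv in rows.items():
        rec = {"variant": variant}
        rec.update({k: fv.values[k] for k in FEATURE_NAMES})
        rec["window_start"] = fv.window_start
        rec["window_end"] = fv.window_end
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


# feature-column synonym normalization for externally produced tables
_COLUMN_SYNONYMS = {
    "rg": "rg",
    "radius_of_gyration": "rg",
    "sasa": "sasa",
    "solvent_accessible_surface_area": "sasa",
    "rmsd": "rmsd",
    "inertia": "inertia",
    "tensor_of_inertia": "inertia",
    "stability": "stability",
    "free_energy_of_stability": "stability",
    "contacts": "contacts",
    "amino_acid_contacts": "contacts",
    "contact_density": "contacts",
    "hbonds": "hbonds",
    "hydrogen_bonds": "hbonds",
    "helix_frac": "helix_frac",
    "alpha_helix": "helix_frac",
    "helix": "helix_frac",
    "sheet_frac": "sheet_frac",
    "beta_sheet": "sheet_frac",
    "sheet": "sheet_frac",
    "coil_frac": "coil_frac",
    "coil": "coil_frac",
    "label": "label",
    "variant": "variant",
}


def _normalize_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_").replace("-", "_")
        if key in _COLUMN_SYNONYMS:
            mapping[col] = _COLUMN_SYNONYMS[key]
    return df.rename(columns=mapping), mapping


def read_feature_workbook(
    path: str | Path, labels_path: str | Path | None = None
) -> pd.DataFrame:
    """Read a feature table (CSV or xlsx workbook), optionally joining a
    separate labels file by row order.

    Column names are normalized through a synonym map (logged via warning);
    a missing feature column or a features/labels row-count mismatch is an
    error.
    """
    path = Path(path)
    reader = pd.read_excel if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv
    df = reader(path)
    df, mapping = _normalize_columns(df)
    renamed = {k: v for k, v in mapping.items() if str(k) != v}
    if renamed:
        warnings.warn(f"normalized feature columns: {renamed}", stacklevel=2)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if labels_path is not None:
        labels_path = Path(labels_path)
        lreader = (
            pd.read_excel
            if labels_path.suffix.lower() in (".xlsx", ".xls")
            else pd.read_csv
        )
        labels = lreader(labels_path)
        labels, _ = _normalize_columns(labels)
        if len(labels) != len(df):
            raise ValueError(
                f"features ({len(df)} rows) and labels ({len(labels)} rows) mismatch"
            )
        label_col = "label" if "label" in labels.columns else labels.columns[-1]
        df = df.copy()
        df["label"] = labels[label_col].to_numpy()
    return df


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path, config: dict, inputs: list[str | Path], seeds: dict
) -> None:
    """Machine-readable run manifest: effective config, seeds, input digests."""
    manifest = {
        "config": config,
        "seeds": seeds,
        "inputs": {
            str(p): sha256_of(p) for p in inputs if Path(p).exists()
        },
    }
    write_json(manifest, path)
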