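"""Structural-MRI feature tables: the 285-name manifest and its parsers.

The manifest fixes the per-subject MRI feature set: 62 subcortical volumes
(ASEG segmentation rows plus whole-brain volume summaries), 148 cortical
thickness/area measures (Desikan-Killiany parcellation per hemisphere plus
hemisphere-level and lobar summaries) and 75 white-matter volumes (wmparc).
It ships as a versioned YAML resource; the exact structure lists are a
documented approximation of a typical morphometry export — downstream
contracts depend on the cardinalities and the naming grammar, not on the
specific structures — and can be replaced via configuration.

Two on-disk encodings are supported and must agree exactly:

* the FreeSurfer stats dialect (``aseg.stats``, ``lh.aparc.stats``,
  ``rh.aparc.stats``, ``wmparc.stats``: ``#`` header lines carrying
  ``Measure`` summaries and ``ColHeaders``, whitespace-delimited body rows);
* a flat two-column TSV (``feature<TAB>value``), the canonical test format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

EXPECTED_COUNTS = {"aseg": 62, "aparc": 148, "wm": 75}


@dataclass(frozen=True)
class MriManifest:
    version: int
    aseg_names: tuple[str, ...]
    aparc_names: tuple[str, ...]
    wm_names: tuple[str, ...]
    aseg_body_names: tuple[str, ...]
    aseg_measure_names: tuple[str, ...]
    dk_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = {"aseg": len(self.aseg_names), "aparc": len(self.aparc_names),
                  "wm": len(self.wm_names)}
        if counts != EXPECTED_COUNTS:
            raise ValueError(f"manifest cardinalities {counts} != {EXPECTED_COUNTS}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("manifest names are not unique")

    @property
    def names(self) -> tuple[str, ...]:
        return self.aseg_names + self.aparc_names + self.wm_names

    def __len__(self) -> int:
        return len(self.names)


def load_manifest() -> MriManifest:
    """Load the shipped manifest resource (asserting 62/148/75 names)."""
    with resources.files("neurofuse.resources").joinpath("mri_manifest.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return MriManifest(
        version=doc["version"],
        aseg_names=tuple(doc["aseg_names"]),
        aparc_names=tuple(doc["aparc_names"]),
        wm_names=tuple(doc["wm_names"]),
        aseg_body_names=tuple(doc["aseg_body_names"]),
        aseg_measure_names=tuple(doc["aseg_measure_names"]),
        dk_regions=tuple(doc["dk_regions"]),
    )


@dataclass
class MriFeatureRow:
    subject_id: str
    values: dict[str, float]

    def as_series(self, manifest: MriManifest) -> pd.Series:
        return pd.Series({n: self.values[n] for n in manifest.names},
                         name=self.subject_id)


# ---------------------------------------------------------------- stats dialect

def _parse_stats_file(path: Path) -> tuple[dict[str, float], list[str], dict[str, str]]:
    """Return (measure token -> value, body lines split, ColHeaders meta)."""
    measures: dict[str, float] = {}
    meta: dict[str, str] = {}
    body: list[list[str]] = []
    col_headers: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("Measure"):
                parts = [p.strip() for p in stripped[len("Measure"):].split(",")]
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed Measure line")
                token = parts[1]
                try:
                    measures[token] = float(parts[3])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric Measure value {parts[3]!r}"
                    ) from exc
            elif stripped.startswith("ColHeaders"):
                col_headers = stripped.split()[1:]
            elif stripped.startswith("hemi"):
                meta["hemi"] = stripped.split()[1]
            continue
        body.append((lineno, line.split()))
    if not col_headers:
        raise ValueError(f"{path}: missing ColHeaders line")
    rows: list[dict[str, str]] = []
    for lineno, parts in body:
        if len(parts) != len(col_headers):
            raise ValueError(
                f"{path}:{lineno}: expected {len(col_headers)} columns, got {len(parts)}")
        rows.append(dict(zip(col_headers, parts)))
    return measures, rows, meta


def _read_volume_table(path: Path, value_col: str) -> dict[str, float]:
    measures, rows, _ = _parse_stats_file(path)
    out = dict(measures)
    for row in rows:
        name = row["StructName"]
        if name in out:
            raise ValueError(f"{path}: duplicate structure {name!r}")
        out[name] = float(row[value_col])
    return out


def _read_aparc_table(path: Path) -> dict[str, float]:
    measures, rows, meta = _parse_stats_file(path)
    hemi = meta.get("hemi")
    if hemi not in ("lh", "rh"):
        raise ValueError(f"{path}: missing or invalid '# hemi' header")
    out = dict(measures)  # measure tokens are full manifest names
    for row in rows:
        base = f"{hemi}-{row['StructName']}"
        for suffix, col in (("thickness", "ThickAvg"), ("area", "SurfArea")):
            name = f"{base}-{suffix}"
            if name in out:
                raise ValueError(f"{path}: duplicate structure {name!r}")
            out[name] = float(row[col])
    return out


def parse_stats_tables(subject_id: str, paths: dict[str, str | Path],
                       manifest: MriManifest | None = None) -> MriFeatureRow:
    """Parse one subject's stats-dialect file set into a manifest-complete row.

    ``paths`` maps ``aseg``, ``lh_aparc``, ``rh_aparc``, ``wmparc`` to files.
    Every manifest name must resolve; unresolved names are reported together.
    Extra structures in the files are ignored with a log entry.
    """
    manifest = manifest or load_manifest()
    found: dict[str, float] = {}
    found.update(_read_volume_table(Path(paths["aseg"]), "Volume_mm3"))
    found.update(_read_aparc_table(Path(paths["lh_aparc"])))
    found.update(_read_aparc_table(Path(paths["rh_aparc"])))
    found.update(_read_volume_table(Path(paths["wmparc"]), "Volume_mm3"))
    return _resolve(subject_id, found, manifest)


def parse_flat_tsv(subject_id: str, path: str | Path,
                   manifest: MriManifest | None = None) -> MriFeatureRow:
    """Parse the canonical flat TSV (columns: feature, value)."""
    manifest = manifest or load_manifest()
    table = pd.read_csv(path, sep="\t")
    if list(table.columns) != ["feature", "value"]:
        raise ValueError(f"{path}: expected columns ['feature', 'value'], "
                         f"got {list(table.columns)}")
    if table["feature"].duplicated().any():
        dups = table["feature"][table["feature"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate features {dups}")
    found = dict(zip(table["feature"], table["value"].astype(float)))
    return _resolve(subject_id, found, manifest)


def _resolve(subject_id: str, found: dict[str, float],
             manifest: MriManifest) -> MriFeatureRow:
    missing = [n for n in manifest.names if n not in found]
    if missing:
        raise KeyError(
            f"subject {subject_id}: {len(missing)} manifest feature(s) unresolved: "
            f"{missing}")
    extra = sorted(set(found) - set(manifest.names))
    if extra:
        log.info("subject %s: ignoring %d non-manifest entries (e.g. %s)",
                 subject_id, len(extra), extra[:3])
    values = {n: float(found[n]) for n in manifest.names}
    bad = [n for n, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"subject {subject_id}: non-finite values for {bad}")
    return MriFeatureRow(subject_id, values)


def assemble_mri_matrix(rows: list[MriFeatureRow],
                        manifest: MriManifest | None = None) -> pd.DataFrame:
    """Stack per-subject rows into a subjects x 285 matrix (input order kept)."""
    manifest = manifest or load_manifest()
    if not rows:
        raise ValueError("no MRI feature rows to assemble")
    ids = [r.subject_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in MRI rows")
    return pd.DataFrame([r.as_series(manifest) for r in rows])


# ---------------------------------------------------------------- writers

def write_flat_tsv(row: MriFeatureRow, path: str | Path,
                   manifest: MriManifest | None = None) -> None:
    manifest = manifest or load_manifest()
    pd.DataFrame({"feature": list(manifest.names),
                  "value": [row.values[n] for n in manifest.names]}
                 ).to_csv(path, sep="\t", index=False)


def write_stats_tables(row: MriFeatureRow, out_dir: str | Path,
                       manifest: MriManifest | None = None) -> dict[str, Path]:
    """Write one subject's values as a FreeSurfer-dialect stats file set."""
    manifest = manifest or load_manifest()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v = row.values

    def measure(token: str, desc: str, unit: str) -> str:
        return f"# Measure {token}, {token}, {desc}, {v[token]:.6f}, {unit}\n"

    aseg = out / "aseg.stats"
    with aseg.open("w") as fh:
        fh.write(f"# Title Segmentation Statistics (subject {row.subject_id})\n")
        for token in manifest.aseg_measure_names:
            fh.write(measure(token, "volume", "mm^3"))
        fh.write("# ColHeaders Index SegId NVoxels Volume_mm3 StructName\n")
        for i, name in enumerate(manifest.aseg_body_names, start=1):
            fh.write(f"{i:3d} {i:4d} {int(v[name])} {v[name]:.1f} {name}\n")

    paths = {"aseg": aseg}
    for hemi in ("lh", "rh"):
        p = out / f"{hemi}.aparc.stats"
        with p.open("w") as fh:
            fh.write(f"# Title Cortical Parcellation Statistics (subject {row.subject_id})\n")
            fh.write(f"# hemi {hemi}\n")
            for name in manifest.aparc_names:
                if name.startswith(f"{hemi}-") and name.split("-", 1)[1].rsplit("-", 1)[0] not in manifest.dk_regions:
                    unit = "mm" if name.endswith("thickness") else "mm^2"
                    fh.write(measure(name, "summary", unit))
            fh.write("# ColHeaders StructName NumVert SurfArea ThickAvg\n")
            for region in manifest.dk_regions:
                area = v[f"{hemi}-{region}-area"]
                thick = v[f"{hemi}-{region}-thickness"]
                fh.write(f"{region} {max(1, int(area))} {area:.1f} {thick:.3f}\n")
        paths[f"{hemi}_aparc"] = p

    wmparc = out / "wmparc.stats"
    with wmparc.open("w") as fh:
        fh.write(f"# Title White Matter Parcellation Statistics (subject {row.subject_id})\n")
        fh.write("# ColHeaders Index SegId NVoxels Volume_mm3 StructName\n")
        for i, name in enumerate(manifest.wm_names, start=1):
            fh.write(f"{i:3d} {3000 + i:4d} {int(v[name])} {v[name]:.1f} {name}\n")
    paths["wmparc"] = wmparc
    return paths
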