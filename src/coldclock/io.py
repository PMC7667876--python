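"""File formats shared by the pipeline stages.

BED6 for polyA-site catalogs (gene id in the name field, species in an
optional seventh column), TSV for read 3'-end tables, long-format CSV for
plate-well bioluminescence profiles, and multi-page TIFF with a JSON sidecar
(voxel sizes, ground truth) for image stacks. An optional SAM/BAM adapter
extracts strand-aware read 3' ends via pysam.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .circadian import WellProfile
from .pasquant import PasSite


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path) -> list[PasSite]:
    """Read a BED6(+species) polyA-site catalog into PasSite records.

    The BED interval is expected to be the 1-nt cleavage position
    ([pos, pos+1)); the name field carries the gene id and an optional
    seventh column the species (default human). Malformed lines raise with
    their line number.
    """
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedFormatError(
                    f"{path}:{ln}: expected >=6 tab-separated BED fields, got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as e:
                raise BedFormatError(f"{path}:{ln}: non-integer coordinates") from e
            if strand not in ("+", "-"):
                raise BedFormatError(f"{path}:{ln}: invalid strand {strand!r}")
            species = parts[6] if len(parts) > 6 else "human"
            # cleavage site: 3'-most base of the 1-nt BED interval
            sites.append(PasSite(chrom, strand, end - 1, name, species))
    return sites


def write_bed(sites: list[PasSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.cleavage_pos}\t{s.cleavage_pos + 1}\t{s.gene_id}\t0\t"
                f"{s.strand}\t{s.species}\n"
            )


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "strand", "pos_3prime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def reads_from_sam(path: str | Path) -> pd.DataFrame:
    """Extract strand-aware 3'-most aligned positions from a SAM/BAM file."""
    import pysam  # optional dependency

    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            pos = aln.reference_start if aln.is_reverse else aln.reference_end - 1
            rows.append((aln.reference_name, strand, pos))
    return pd.DataFrame(rows, columns=["chrom", "strand", "pos_3prime"])


# ---------------------------------------------------------------------------
# plate profiles

_PROFILE_COLS = ["well_id", "genotype", "group", "time_h", "signal", "is_control"]


def write_profiles_csv(wells: list[WellProfile], path: str | Path) -> None:
    frames = []
    for w in wells:
        cw = w.cold_window or (np.nan, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "genotype": w.genotype,
                    "group": w.phase_group,
                    "time_h": w.time_h,
                    "signal": w.signal,
                    "is_control": w.is_control,
                    "cold_start_h": cw[0],
                    "cold_end_h": cw[1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[WellProfile]:
    df = pd.read_csv(path)
    missing = set(_PROFILE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wells = []
    for wid, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        cw = (
            None
            if grp["cold_start_h"].isna().all()
            else (float(grp["cold_start_h"].iloc[0]), float(grp["cold_end_h"].iloc[0]))
        )
        wells.append(
            WellProfile(
                well_id=str(wid),
                time_h=grp["time_h"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                genotype=str(grp["genotype"].iloc[0]),
                phase_group=str(grp["group"].iloc[0]),
                cold_window=cw,
                is_control=bool(grp["is_control"].iloc[0]),
            )
        )
    return wells


# ---------------------------------------------------------------------------
# image stacks

def write_stack(
    path: str | Path,
    data: np.ndarray,
    voxel_size: tuple[float, ...] | None = None,
    ground_truth: dict | None = None,
) -> None:
    """Write a TIFF stack plus a JSON sidecar with voxel sizes and truth."""
    tifffile.imwrite(str(path), np.asarray(data), photometric="minisblack")
    sidecar = {"voxel_size_um": voxel_size, "ground_truth": _jsonable(ground_truth)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    data = tifffile.imread(str(path))
    side = Path(str(path) + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return data, meta


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
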