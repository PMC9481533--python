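"""Virtual-screen bookkeeping: docking boxes, z-scores, consensus ranking.

Docking engines emit scores in their own energy units with lower = stronger
binding. Scores are standardized per engine (z = (score - mean) / sd over the
screened library), a consensus z is the unweighted mean over engines, and
hits are the compounds whose consensus z falls at least the stated number of
standard deviations below the library average (z <= -2 selects compounds
">2 SD stronger than the average").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError, SelectionError
from .structure import FibrilStructure

#: default search-volume extents (Angstrom) for the grid-box engine, matching
#: the inter-protofilament cleft site
DEFAULT_BOX_EXTENTS = (20.0, 16.0, 12.0)
#: default edge for the sphere/cube-style engine
DEFAULT_BOX_EDGE = 7.0

SCORE_COLUMNS = ["compound", "engine", "score"]


@dataclass(frozen=True)
class SiteBox:
    """Docking search volume centered on a binding site."""

    center: tuple[float, float, float]
    extents: tuple[float, float, float]
    engine: str

    def __post_init__(self):
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"box extents must be > 0, got {self.extents}")


def site_box_from_ligand(
    structure: FibrilStructure,
    ligand_selection: np.ndarray,
    engine: str = "grid",
    padding: float = 0.0,
    extents: tuple[float, float, float] | None = None,
    edge: float = DEFAULT_BOX_EDGE,
) -> SiteBox:
    """Box centered on the bound-ligand centroid.

    ``grid`` engines get explicit x/y/z extents (defaulting to the ligand
    bounding box plus ``2 * padding``, or the shipped cleft-site default when
    ``extents`` is given as ``"default"``); ``sphere`` engines get a single
    edge parameter passed through verbatim.
    """
    sel = np.asarray(ligand_selection, dtype=bool)
    if not sel.any():
        raise SelectionError("ligand selection is empty")
    if padding < 0:
        raise ValueError("padding must be >= 0")
    coords = structure.coord[sel]
    center = tuple(float(x) for x in coords.mean(axis=0))
    if engine == "sphere":
        return SiteBox(center=center, extents=(edge, edge, edge), engine=engine)
    if extents is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        ext = tuple(float(s + 2 * padding) for s in span)
    else:
        ext = tuple(float(e) for e in extents)
    return SiteBox(center=center, extents=ext, engine=engine)


def write_grid_config(box: SiteBox, path: str | Path) -> None:
    """Key/value text config (center_* / size_*) for a grid-box engine."""
    with open(path, "w") as fh:
        for k, v in zip(("x", "y", "z"), box.center):
            fh.write(f"center_{k} = {v:.3f}\n")
        for k, v in zip(("x", "y", "z"), box.extents):
            fh.write(f"size_{k} = {v:.3f}\n")


def write_sphere_config(box: SiteBox, path: str | Path) -> None:
    """Options-file dialect for the site-sphere engine (edge passed verbatim)."""
    with open(path, "w") as fh:
        fh.write(
            "site_center = {:.3f} {:.3f} {:.3f}\n".format(*box.center)
        )
        fh.write(f"site_edge = {box.extents[0]:.3f}\n")


# -- score tables -----------------------------------------------------------


def read_scores(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited compound/engine/score table (TSV or CSV)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SelectionError(f"score table lacks columns: {missing}")
    return df


def zscore_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize scores per engine and rank by consensus z.

    Requires >= 3 scores per engine and one score per (compound, engine).
    Returns one row per compound with per-engine z columns (``z_<engine>``),
    ``consensus_z`` (unweighted mean over available engines) and ``rank``
    (1 = most negative consensus z; ties broken by compound id).
    """
    for col in SCORE_COLUMNS:
        if col not in table.columns:
            raise SelectionError(f"score table lacks column {col!r}")
    dup = table.duplicated(subset=["compound", "engine"])
    if dup.any():
        raise SelectionError("multiple scores for one (compound, engine) pair")
    work = table.copy()
    for engine, grp in work.groupby("engine"):
        if len(grp) < 3:
            raise SelectionError(f"engine {engine!r} has < 3 scores")
        sd = float(grp["score"].std(ddof=1))
        if sd == 0:
            raise DegenerateDistributionError(
                f"engine {engine!r} scores have zero standard deviation"
            )
        work.loc[grp.index, "z"] = (grp["score"] - grp["score"].mean()) / sd
    wide = work.pivot(index="compound", columns="engine", values="z")
    wide.columns = [f"z_{c}" for c in wide.columns]
    wide["consensus_z"] = wide.mean(axis=1)
    keep = [c for c in table.columns if c not in {"engine", "score"} and c != "compound"]
    if keep:
        extras = table.drop_duplicates("compound").set_index("compound")[keep]
        wide = wide.join(extras)
    wide = wide.sort_values(
        ["consensus_z", "compound"], ascending=[True, True],
        key=lambda s: s if s.name == "consensus_z" else s.astype(str),
    ).reset_index()
    wide["rank"] = np.arange(1, len(wide) + 1)
    return wide


def select_hits(
    ranked: pd.DataFrame,
    z_threshold: float = -2.0,
    top_n: int | None = None,
    control_compounds: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Compounds with consensus z at or below the threshold, truncated to top_n.

    Control compounds (e.g. the known binder spiked into the library) are
    flagged in an ``is_control`` column but not removed — a control clearing
    the threshold is the screen's positive-control check.
    """
    if "consensus_z" not in ranked.columns:
        raise SelectionError("table is not ranked: run zscore_rank first")
    hits = ranked[ranked["consensus_z"] <= z_threshold].copy()
    hits = hits.sort_values("rank")
    if top_n is not None:
        hits = hits.head(max(int(top_n), 0))
    hits["is_control"] = hits["compound"].isin(control_compounds)
    return hits.reset_index(drop=True)
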