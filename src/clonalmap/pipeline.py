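"""End-to-end pipeline and text writers.

The analysis runs in four steps: (1) estimate all pairwise recombination
frequencies, (2) determine linkage phases from the estimates, (3) group and
order markers and build the combined/female/male maps, (4) build the four
parental haploids and re-emit the population as a phase-known double cross.
All outputs are plain delimited text.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .estimation import RecombMatrix, estimate_all_pairs
from .haploids import HaploidSet, build_haploids, canonicalize_to_double_cross
from .mapping import (
    GroupingResult,
    LinkageMap,
    MapFunction,
    MapKind,
    build_maps,
    group_markers,
    order_markers,
)
from .markers import GenotypeMatrix, PopulationType, read_genotype_file, write_genotype_file

logger = logging.getLogger("clonalmap")

_NA = "NA"


@dataclass
class RunConfig:
    input_path: Path | None = None
    population: PopulationType = PopulationType.CLONAL_F1
    threshold: float = 0.3
    mapfn: MapFunction = MapFunction.HALDANE
    alpha: float = 0.05
    out_dir: Path = Path("clonalmap_out")


@dataclass
class PipelineResult:
    genotypes: GenotypeMatrix
    segregation: pd.DataFrame
    rm: RecombMatrix
    grouping: GroupingResult
    orders: list[list[str]]
    maps: list[dict[MapKind, LinkageMap]]
    haploid_sets: list[HaploidSet]
    double_cross: GenotypeMatrix | None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def excluded_markers(self) -> list[str]:
        return list(self.grouping.singletons)


def run_pipeline(gm: GenotypeMatrix, cfg: RunConfig | None = None) -> PipelineResult:
    """Run estimate -> group -> order -> map -> haploids on a genotype matrix."""
    cfg = cfg or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    segregation = gm.segregation_screen(cfg.alpha)
    n_distorted = int(segregation["distorted"].sum())
    if n_distorted:
        logger.info("%d markers show segregation distortion (alpha=%g); flagged, retained",
                    n_distorted, cfg.alpha)
    timings["segregation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rm = estimate_all_pairs(gm)
    timings["estimation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grouping = group_markers(rm, cfg.threshold)
    for m in grouping.singletons:
        logger.info("marker %s cannot be linked with any other marker; excluded from maps", m)
    orders = [order_markers(g, rm) for g in grouping.groups]
    timings["grouping_ordering"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    maps = [build_maps(order, rm, cfg.mapfn) for order in orders]
    timings["maps"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    haploid_sets = [build_haploids(order, rm) for order in orders]
    double_cross: GenotypeMatrix | None = None
    if gm.population is PopulationType.CLONAL_F1 and haploid_sets:
        dc = gm
        canon_sets = []
        for hs in haploid_sets:
            dc, hs_c = canonicalize_to_double_cross(dc, hs)
            canon_sets.append(hs_c)
        double_cross = dc
    timings["haploids"] = time.perf_counter() - t0

    return PipelineResult(
        genotypes=gm,
        segregation=segregation,
        rm=rm,
        grouping=grouping,
        orders=orders,
        maps=maps,
        haploid_sets=haploid_sets,
        double_cross=double_cross,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# Writers (tab-delimited; NA for inestimable cells)
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.6f")


def read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])


def write_maps(maps: list[dict[MapKind, LinkageMap]], rm: RecombMatrix, path: Path) -> None:
    """One row per marker per map: group, kind, marker, category, position (2 d.p.)."""
    with Path(path).open("w") as fh:
        fh.write("group\tmap\tmarker\tcategory\tposition_cM\tflagged\n")
        for gid, group_maps in enumerate(maps, start=1):
            for kind in (MapKind.COMBINED, MapKind.FEMALE, MapKind.MALE):
                lm = group_maps[kind]
                flags = [False] + list(lm.interval_flagged)
                for marker, pos, fl in zip(lm.markers, lm.positions, flags):
                    cat = rm.category(marker).name
                    fh.write(
                        f"{gid}\t{kind.value}\t{marker}\t{cat}\t{pos:.2f}\t{int(fl)}\n"
                    )


def read_maps(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_haploids(haploid_sets: list[HaploidSet], path: Path) -> None:
    frames = []
    for gid, hs in enumerate(haploid_sets, start=1):
        df = hs.table.copy()
        df.insert(0, "group", gid)
        frames.append(df)
    out = pd.concat(frames) if frames else pd.DataFrame()
    out.to_csv(path, sep="\t")


def write_groups(grouping: GroupingResult, path: Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("group\tmarker\n")
        for gid, g in enumerate(grouping.groups, start=1):
            for m in g.members:
                fh.write(f"{gid}\t{m}\n")
        for m in grouping.singletons:
            fh.write(f"unlinked\t{m}\n")


def write_artifacts(result: PipelineResult, out_dir: Path) -> list[Path]:
    """Write every pipeline artifact under out_dir; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rm = result.rm
    written = []
    for name, df in (
        ("r_combined", rm.r),
        ("r_female", rm.r_f),
        ("r_male", rm.r_m),
        ("lod", rm.lod),
    ):
        path = out_dir / f"{name}.tsv"
        write_matrix(df, path)
        written.append(path)
    path = out_dir / "segregation.tsv"
    result.segregation.to_csv(path, sep="\t")
    written.append(path)
    path = out_dir / "groups.tsv"
    write_groups(result.grouping, path)
    written.append(path)
    path = out_dir / "maps.tsv"
    write_maps(result.maps, rm, path)
    written.append(path)
    path = out_dir / "haploids.tsv"
    write_haploids(result.haploid_sets, path)
    written.append(path)
    if result.double_cross is not None:
        path = out_dir / "double_cross_genotypes.tsv"
        write_genotype_file(result.double_cross, path)
        written.append(path)
    with (out_dir / "run_log.txt").open("w") as fh:
        for stage, sec in result.timings.items():
            fh.write(f"{stage}\t{sec:.3f}s\n")
        for m in result.excluded_markers:
            fh.write(f"excluded\t{m}\tunlinked to all other markers\n")
    written.append(out_dir / "run_log.txt")
    return written


def run_file(path: str | Path, cfg: RunConfig | None = None) -> PipelineResult:
    cfg = cfg or RunConfig()
    gm = read_genotype_file(path, cfg.population)
    return run_pipeline(gm, cfg)
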