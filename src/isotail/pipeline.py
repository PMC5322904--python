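"""End-to-end orchestration: simulate/load -> classify -> quantify -> compare.

A run is driven by one YAML config and writes a directory of TSVs plus a file
manifest with checksums; reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cl
from . import compare as cp
from . import quantify as qt
from . import refsets as rs
from . import synthetic as sy

log = logging.getLogger("isotail")

ASSAY_ROLES = ("in_vivo", "IP_mock", "IP_SDN1", "IP_SDN1_D283A")

__all__ = ["LibrarySpec", "RunConfig", "load_config", "validate", "run"]


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    genotype: str
    replicate: int = 1
    assay_role: str = "in_vivo"
    path: str | None = None  # FASTQ/FASTA on disk ...
    simulate: str | None = None  # ... or a preset profile name
    library_size: int = 50_000


@dataclass
class RunConfig:
    libraries: list[LibrarySpec]
    output_dir: str = "isotail_run"
    seed: int = 0
    mature_fasta: str | None = None
    hairpin_fasta: str | None = None
    offsets: str | None = None
    classify_params: cl.ClassifyParams = field(default_factory=cl.ClassifyParams)
    rpm_threshold: float = 10.0
    rpm_denominator: str = "length_filtered_total"  # or "assigned_total"
    contrasts: list[dict] = field(default_factory=list)
    linkage: str = "average"
    error_rate: float = 0.0
    background_fraction: float = 0.0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    libs = [
        LibrarySpec(
            library_id=d["id"],
            genotype=d.get("genotype", d["id"]),
            replicate=int(d.get("replicate", 1)),
            assay_role=d.get("assay_role", "in_vivo"),
            path=d.get("path"),
            simulate=d.get("simulate"),
            library_size=int(d.get("library_size", 50_000)),
        )
        for d in raw.get("libraries", [])
    ]
    cp_raw = raw.get("classify", {})
    params = cl.ClassifyParams(**cp_raw) if cp_raw else cl.ClassifyParams()
    ref = raw.get("reference", {})
    return RunConfig(
        libraries=libs,
        output_dir=raw.get("output_dir", "isotail_run"),
        seed=int(raw.get("seed", 0)),
        mature_fasta=ref.get("mature_fasta"),
        hairpin_fasta=ref.get("hairpin_fasta"),
        offsets=ref.get("offsets"),
        classify_params=params,
        rpm_threshold=float(raw.get("thresholds", {}).get("rpm", 10.0)),
        rpm_denominator=raw.get("rpm_denominator", "length_filtered_total"),
        contrasts=raw.get("contrasts", []),
        linkage=raw.get("linkage", "average"),
        error_rate=float(raw.get("error_rate", 0.0)),
        background_fraction=float(raw.get("background_fraction", 0.0)),
    )


def validate(config: RunConfig) -> list[str]:
    """All structural problems at once; empty list means the config is runnable."""
    problems: list[str] = []
    ids = [l.library_id for l in config.libraries]
    if not ids:
        problems.append("no libraries configured")
    for i in sorted({x for x in ids if ids.count(x) > 1}):
        problems.append(f"duplicate library id {i!r}")
    genotypes = {l.genotype for l in config.libraries}
    for l in config.libraries:
        if l.replicate < 1:
            problems.append(f"library {l.library_id!r}: replicate index must be >= 1")
        if l.assay_role not in ASSAY_ROLES:
            problems.append(
                f"library {l.library_id!r}: unknown assay_role {l.assay_role!r}"
            )
        if l.path is None and l.simulate is None:
            problems.append(
                f"library {l.library_id!r}: needs either 'path' or 'simulate'"
            )
        if l.path is not None and not Path(l.path).exists():
            problems.append(f"library {l.library_id!r}: missing file {l.path}")
        if l.simulate is not None and l.simulate not in sy.preset_profiles():
            problems.append(
                f"library {l.library_id!r}: unknown preset {l.simulate!r}"
            )
    for c in config.contrasts:
        for side in ("a", "b"):
            if c.get(side) not in genotypes:
                problems.append(f"contrast references unknown genotype {c.get(side)!r}")
    for p in (config.mature_fasta, config.hairpin_fasta, config.offsets):
        if p is not None and not Path(p).exists():
            problems.append(f"missing reference file {p}")
    return problems


def _load_reads(spec: LibrarySpec, refset: rs.ReferenceSet, config: RunConfig):
    if spec.simulate is not None:
        profiles = sy.preset_profiles(
            refset.group_names,
            library_size=spec.library_size,
            error_rate=config.error_rate,
            background_fraction=config.background_fraction,
        )
        reads, manifest = sy.generate_library(
            profiles[spec.simulate], refset, spec.library_id, config.seed
        )
        return reads, manifest
    path = Path(spec.path)  # type: ignore[arg-type]
    if path.suffix.lower() in (".fq", ".fastq"):
        return list(cl.read_fastq(path)), None
    return list(cl.read_collapsed_fasta(path)), None


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(f"- {p}" for p in problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mature_fasta:
        refset = rs.load_references(
            config.mature_fasta, config.hairpin_fasta, config.offsets
        )
    else:
        refset = sy.demo_reference()
    params = config.classify_params

    calls_by_lib: dict[str, list[cl.IsoformCall]] = {}
    stats_by_lib: dict[str, cl.LibraryStats] = {}
    comp_tables = []
    for spec in config.libraries:
        reads, manifest = _load_reads(spec, refset, config)
        calls, stats = cl.classify_library(reads, refset, params)
        calls_by_lib[spec.library_id] = calls
        stats_by_lib[spec.library_id] = stats
        log.info(
            "%s: %d reads, %.0f assigned, %.0f unassigned, %.0f ambiguous, "
            "%.0f length-filtered",
            spec.library_id, int(stats.total), stats.assigned,
            stats.unassigned, stats.ambiguous_dropped, stats.length_filtered,
        )
        cl.write_calls_tsv(out / f"calls_{spec.library_id}.tsv", spec.library_id, calls)
        if manifest is not None:
            manifest.to_csv(out / f"manifest_{spec.library_id}.tsv", sep="\t", index=False)
        denom = (
            stats.assigned
            if config.rpm_denominator == "assigned_total"
            else stats.denominator
        )
        comp_tables.append(qt.compose(calls, denom, spec.library_id))
    composition = pd.concat(comp_tables, ignore_index=True)
    composition.to_csv(out / "composition.tsv", sep="\t", index=False)

    in_vivo = [l for l in config.libraries if l.assay_role == "in_vivo"]
    kept: list[str] = []
    if in_vivo:
        sub = composition[composition["library_id"].isin([l.library_id for l in in_vivo])]
        kept = qt.abundance_filter(sub, config.rpm_threshold)
        pd.Series(kept, name="group_name").to_csv(
            out / "abundant_groups.tsv", sep="\t", index=False
        )
        log.info("abundance filter (RPM > %g): %d groups kept", config.rpm_threshold, len(kept))

    # truncation-tailing matrices for abundant groups
    mats = []
    for spec in config.libraries:
        for g in kept:
            calls = [c for c in calls_by_lib[spec.library_id] if c.group_name == g]
            if not calls:
                continue
            m = qt.build_matrix(calls, g, params.max_tr, params.max_ta)
            mats.append(qt.matrix_long(m, spec.library_id, g))
    if mats:
        pd.concat(mats, ignore_index=True).to_csv(
            out / "matrices.tsv", sep="\t", index=False
        )

    # binding fractions for IP libraries
    ip_libs = [l for l in config.libraries if l.assay_role.startswith("IP_")]
    if ip_libs:
        bf = {
            l.library_id: qt.binding_fraction(calls_by_lib[l.library_id])
            for l in ip_libs
            if calls_by_lib[l.library_id]
        }
        if bf:
            pd.DataFrame(bf).fillna(0.0).rename_axis("group_name").to_csv(
                out / "binding_fractions.tsv", sep="\t"
            )
        _ip_assay_tables(config, calls_by_lib, out)

    # genotype contrasts on per-replicate compositions
    if config.contrasts:
        rows = []
        by_genotype: dict[str, list[str]] = {}
        for l in in_vivo:
            by_genotype.setdefault(l.genotype, []).append(l.library_id)
        with_ratios = composition.assign(
            truncation_ratio=composition.apply(qt.truncation_ratio, axis=1),
            tronly_ratio=composition.apply(qt.tronly_ratio, axis=1),
        )
        for c in config.contrasts:
            metrics = c.get("metrics", ["p_TR", "p_TRTA"])
            libs_a = by_genotype.get(c["a"], [])
            libs_b = by_genotype.get(c["b"], [])
            for g in kept or sorted(with_ratios["group_name"].unique()):
                sub = with_ratios[with_ratios["group_name"] == g].set_index("library_id")
                for metric in metrics:
                    va = [sub.at[x, metric] for x in libs_a if x in sub.index]
                    vb = [sub.at[x, metric] for x in libs_b if x in sub.index]
                    if not va or not vb:
                        continue
                    res = cp.two_group_test(va, vb, group_name=g, metric_name=metric)
                    rows.append(
                        {"contrast": f"{c['a']}_vs_{c['b']}", **dataclasses.asdict(res)}
                    )
        if rows:
            pd.DataFrame(rows).to_csv(out / "contrasts.tsv", sep="\t", index=False)

    # library clustering on log2(RPM + 1) at (group, category) resolution:
    # genotypes often share abundance profiles and differ only in isoform
    # composition, which group totals alone cannot see
    if len(config.libraries) >= 2:
        rpm_wide = category_rpm_table(composition)
        dist, newick = cp.cluster_libraries(rpm_wide, config.linkage)
        dist.rename_axis("library_id").to_csv(out / "distances.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(newick + "\n")

    _write_manifest(out, config)
    return out


def category_rpm_table(composition: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, category) RPM, rows x libraries, for library clustering."""
    frames = []
    for cat, pcol in (("FL", "p_FL"), ("TR_ONLY", "p_TR"),
                      ("TA_ONLY", "p_TA"), ("TR_TA", "p_TRTA")):
        sub = composition[["library_id", "group_name"]].copy()
        sub["feature"] = composition["group_name"] + ":" + cat
        sub["rpm"] = composition["rpm_total"] * composition[pcol]
        frames.append(sub[["library_id", "feature", "rpm"]])
    long = pd.concat(frames, ignore_index=True)
    return long.pivot_table(
        index="feature", columns="library_id", values="rpm", fill_value=0.0
    )


def _ip_assay_tables(config: RunConfig, calls_by_lib, out: Path) -> None:
    """Mock/catalytic-mutant subtraction and TR/FL ratios for IP assays.

    Replicates of each role are pooled at count level, the mock composition is
    subtracted from the SDN1 and SDN1-D283A compositions, and TR-only/FL
    ratios of the adjusted tables are written side by side.
    """
    by_role: dict[str, list] = {}
    for l in config.libraries:
        if l.assay_role.startswith("IP_"):
            by_role.setdefault(l.assay_role, []).append(calls_by_lib[l.library_id])
    if "IP_mock" not in by_role:
        return
    pooled = {role: cp.pool_replicates(call_lists) for role, call_lists in by_role.items()}
    comps = {role: qt.compose(calls, max(sum(c.count for c in calls), 1), role)
             for role, calls in pooled.items()}
    mock = comps["IP_mock"]
    frames = []
    for role in ("IP_SDN1", "IP_SDN1_D283A"):
        if role not in comps:
            continue
        # only the truncated species carried over from the IP input are
        # subtracted, on the proportions-of-group scale; FL stays untouched
        # so the TR/FL readout keeps its denominator
        adj = cp.mock_subtract(comps[role], mock, columns=("p_TR", "p_TRTA"))
        adj["tr_vs_fl"] = adj["p_TR"] / adj["p_FL"].where(adj["p_FL"] > 0)
        adj.insert(0, "role", role)
        frames.append(adj)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out / "ip_assay_tr_vs_fl.tsv", sep="\t", index=False
        )


def _write_manifest(out: Path, config: RunConfig) -> None:
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "run_manifest.json")
    manifest = {
        "seed": config.seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
        },
        "classify_params": dataclasses.asdict(config.classify_params),
        "rpm_threshold": config.rpm_threshold,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
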