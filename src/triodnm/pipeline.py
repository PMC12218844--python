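"""End-to-end orchestration: pedigree check -> violations -> filters ->
validation -> rates -> spectrum -> phasing -> landscape.

`run_analysis` works on in-memory records (what the simulator hands over and
what the tests use); `run_pipeline` is the file-driven wrapper behind the
command line: it reads the VCF/pedigree/FASTA/GFF3/map/evidence inputs named
in a :class:`PipelineConfig`, runs the same analysis, and writes the TSV/JSON
output set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calling, landscape, phasing, rates, spectrum
from .calling import FilterConfig
from .io import (
    Transcript,
    read_bed,
    read_fasta,
    read_gff3,
    read_linkage_map,
    read_pedigree,
    read_read_evidence,
    read_vcf,
    write_bed,
)
from .model import DnmCandidate, ReadEvidence, SiteRecord, Trio

log = logging.getLogger("triodnm")


@dataclass
class PipelineConfig:
    """Paths and knobs of one pipeline run (YAML-loadable)."""

    vcf: str
    pedigree: str
    survey: Optional[str] = None
    fasta: Optional[str] = None
    gff3: Optional[str] = None
    repeats_bed: Optional[str] = None
    linkage_map: Optional[str] = None
    evidence: Optional[str] = None
    out_dir: str = "triodnm_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = landscape.WINDOW_SIZE
    window_step: int = landscape.WINDOW_STEP
    generation_time: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_step > self.window_size:
            raise ValueError("window step must not exceed window size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filt, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_analysis(
    records: Sequence[SiteRecord],
    trios: Sequence[Trio],
    filt: FilterConfig,
    survey: Optional[Sequence[SiteRecord]] = None,
    evidence: Optional[Sequence[ReadEvidence]] = None,
    reference: Optional[dict[str, str]] = None,
    transcripts: Optional[Sequence[Transcript]] = None,
    map_df: Optional[pd.DataFrame] = None,
    repeats: Optional[Sequence[tuple[str, int, int]]] = None,
    window_size: int = landscape.WINDOW_SIZE,
    window_step: int = landscape.WINDOW_STEP,
    generation_time: float = 3.0,
    seed: int = 0,
) -> dict:
    """Run every analysis stage the supplied inputs support.

    Returns a bundle with the funnel counts, candidates, validation,
    callable/FNR summaries, rate estimates, spectrum, phasing and landscape
    sections; stages missing their inputs record a skipped status instead
    of failing the run.
    """
    records = list(records)
    bundle: dict = {"stages": {}}
    blacklist = set(filt.chromosome_blacklist)

    # ---- pedigree check ----------------------------------------------------
    try:
        ped_reports = []
        for trio in trios:
            ped_reports.extend(calling.verify_pedigree(records, trio))
        bundle["pedigree_check"] = ped_reports
        bundle["stages"]["pedigree"] = "ok"
    except Exception as exc:
        raise StageError("pedigree", exc)

    # ---- candidate calling and validation ----------------------------------
    funnel: dict = {}
    candidates = calling.call_candidates(records, trios, filt, funnel)
    passing = [c for c in candidates if c.passed_filters]
    if evidence is not None:
        validation = calling.validate_candidates(passing, evidence, filt)
        fdr = validation.fdr
    else:
        validation = None
        for c in passing:
            c.validation = "validated"
        fdr = 0.0
    curated = [c for c in passing if c.validation == "validated"]
    bundle["funnel"] = funnel
    bundle["candidates"] = candidates
    bundle["validation"] = validation
    bundle["stages"]["calling"] = "ok"

    # ---- callable size and FNR ---------------------------------------------
    if reference is not None:
        autosome_total = float(sum(
            len(s) for c, s in reference.items() if c not in blacklist
        ))
    else:
        autosome_total = None
    callable_by_child = {}
    fnr_by_trio = {}
    for trio in trios:
        stream = survey if survey is not None else records
        callable_by_child[trio.child] = calling.compute_callable_size(
            stream, trio, filt, autosome_total=autosome_total
        )
        fnr_by_trio[trio.child] = calling.estimate_fnr(records, trio, filt)
    ok_fnrs = [f.fnr for f in fnr_by_trio.values() if f.status == "ok"]
    mean_fnr = float(np.mean(ok_fnrs)) if ok_fnrs else 0.0
    if not ok_fnrs:
        log.warning("no trio had enough obligate-het sites; FNR set to 0")
    bundle["callable"] = callable_by_child
    bundle["fnr"] = fnr_by_trio
    bundle["mean_fnr"] = mean_fnr

    # ---- sharing and unique DNMs -------------------------------------------
    groups, sharing = calling.group_shared(curated)
    unique_dnms = [g[0] for g in groups]
    bundle["sharing"] = sharing
    bundle["unique_dnms"] = unique_dnms

    # ---- rates ---------------------------------------------------------------
    curated_counts = {t.child: 0 for t in trios}
    for c in curated:
        curated_counts[c.trio.child] += 1
    children = [t.child for t in trios]
    counts_vec = [curated_counts[ch] for ch in children]
    cs_vec = [callable_by_child[ch].cs for ch in children]
    fnr_vec = [
        fnr_by_trio[ch].fnr if fnr_by_trio[ch].status == "ok" else mean_fnr
        for ch in children
    ]
    if all(cs > 0 for cs in cs_vec):
        estimates = rates.cohort_rates(counts_vec, cs_vec, fdr=0.0,
                                       fnrs=fnr_vec, seed=seed)
        mu_pooled = estimates["pooled_zero_inflated"]
        bundle["rates"] = estimates
        bundle["yearly_rate"] = rates.yearly_rate(mu_pooled, generation_time)
        bundle["stages"]["rates"] = "ok"
    else:
        bundle["rates"] = None
        bundle["stages"]["rates"] = "skipped_no_callable"

    # ---- spectrum and context ----------------------------------------------
    if reference is not None:
        bundle["spectrum"] = spectrum_stage(
            unique_dnms, curated, reference, blacklist,
            transcripts=transcripts, repeats=repeats,
            cs_vec=cs_vec if bundle["rates"] is not None else None,
            mean_fnr=mean_fnr,
        )
        bundle["stages"]["spectrum"] = "ok"
    else:
        bundle["spectrum"] = None
        bundle["stages"]["spectrum"] = "skipped_no_reference"

    # ---- phasing -------------------------------------------------------------
    if evidence is not None:
        bundle["phasing"] = phasing_stage(groups, records, evidence)
        bundle["stages"]["phasing"] = "ok"
    else:
        bundle["phasing"] = None
        bundle["stages"]["phasing"] = "skipped_no_evidence"

    # ---- landscape -----------------------------------------------------------
    if reference is not None:
        mean_callable_frac = (
            float(np.mean([callable_by_child[ch].callable_fraction
                           for ch in children]))
            if autosome_total else 1.0
        )
        try:
            bundle["landscape"] = landscape_stage(
                unique_dnms, reference, blacklist, transcripts=transcripts,
                map_df=map_df, callable_fraction=mean_callable_frac,
                window_size=window_size, window_step=window_step,
            )
            bundle["stages"]["landscape"] = "ok"
        except Exception as exc:
            bundle["landscape"] = None
            bundle["stages"]["landscape"] = f"skipped ({exc})"
    else:
        bundle["landscape"] = None
        bundle["stages"]["landscape"] = "skipped_no_reference"

    bundle["summary"] = summarize(bundle)
    return bundle


def spectrum_stage(
    unique_dnms: Sequence[DnmCandidate],
    curated: Sequence[DnmCandidate],
    reference: dict[str, str],
    blacklist: set[str],
    transcripts: Optional[Sequence[Transcript]] = None,
    repeats: Optional[Sequence[tuple[str, int, int]]] = None,
    cs_vec: Optional[Sequence[float]] = None,
    mean_fnr: float = 0.0,
) -> dict:
    """Spectrum classification, GC bias, CGI detection and DNM annotation."""
    autosome_total = float(sum(
        len(s) for c, s in reference.items() if c not in blacklist
    ))
    muts = []
    for d in unique_dnms:
        ctx = spectrum.trinucleotide_context(reference, d.chrom, d.pos)
        cls, _ = spectrum.classify_mutation(d.ref, d.alt, ctx)
        d.context = cls
        muts.append((d.ref, d.alt, ctx))
    counts = spectrum.build_spectrum(muts)
    gc_total = sum(
        s.count("G") + s.count("C")
        for c, s in reference.items() if c not in blacklist
    )
    gc_fraction = gc_total / autosome_total if autosome_total else 0.0
    section: dict = {"spectrum": counts, "gc_fraction": gc_fraction}
    try:
        section["ts_tv"] = spectrum.ts_tv_ratio(counts)
    except ZeroDivisionError:
        section["ts_tv"] = None
    try:
        section["sw_bias"] = spectrum.sw_bias_test(
            [(d.ref, d.alt) for d in unique_dnms], gc_fraction
        )
    except ValueError:
        section["sw_bias"] = None
    islands = []
    for chrom, seq in reference.items():
        if chrom in blacklist:
            continue
        islands.extend(spectrum.detect_cpg_islands(seq, chrom))
    if transcripts is not None:
        index = spectrum.FeatureIndex(transcripts)
        for isl in islands:
            isl.cgi_class = spectrum.classify_cgi(isl, index)
        repeat_trees = (spectrum.repeats_to_trees(repeats)
                        if repeats is not None else None)
        features = {}
        for d in unique_dnms:
            ann = spectrum.annotate_feature(
                d.chrom, d.pos, d.alt, index, reference, repeat_trees
            )
            features[f"{d.trio.child}:{d.chrom}:{d.pos}"] = ann
        section["features"] = features
    section["cgi"] = islands
    if islands and cs_vec is not None:
        mask: dict[str, list] = {}
        for isl in islands:
            mask.setdefault(isl.chrom, []).append((isl.start, isl.end))
        cgi_bp = sum(e - s for ivs in mask.values() for s, e in ivs)
        frac = cgi_bp / autosome_total
        masked_cs = [cs * frac for cs in cs_vec]
        try:
            section["cgi_rate"] = rates.stratified_rate(
                [(c.chrom, c.pos) for c in curated], mask, masked_cs, mean_fnr
            )
        except ValueError:
            section["cgi_rate"] = None
    return section


def phasing_stage(
    groups: Sequence[Sequence[DnmCandidate]],
    records: Sequence[SiteRecord],
    evidence: Sequence[ReadEvidence],
    phase_cfg: Optional[phasing.PhaseConfig] = None,
) -> dict:
    """Read-backed origin phasing of unique DNMs plus alpha and bias tests."""
    if phase_cfg is None:
        phase_cfg = phasing.PhaseConfig()
    by_chrom: dict[str, list[SiteRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    ev_by_locus: dict[tuple[str, int], list[ReadEvidence]] = {}
    for frag in evidence:
        for chrom, pos, _ in frag.observations:
            ev_by_locus.setdefault((chrom, pos), []).append(frag)
    results = []
    shared_ids = set()
    cpg_ids = set()
    for grp in groups:
        d = grp[0]
        nearby = [
            r for r in by_chrom.get(d.chrom, [])
            if abs(r.pos - d.pos) <= phase_cfg.window
        ]
        info = phasing.find_informative_sites(d, nearby, phase_cfg.window)
        frags = ev_by_locus.get((d.chrom, d.pos), [])
        res = phasing.phase_dnm(d, info, frags, phase_cfg)
        d.origin = res.origin
        results.append(res)
        if len(grp) > 1:
            shared_ids.add(res.dnm_id)
        if d.context == "C>T_CpG":
            cpg_ids.add(res.dnm_id)
    section: dict = {"results": results}
    phased = [r for r in results if r.origin != "unknown"]
    section["phaseable_fraction"] = (
        len(phased) / len(results) if results else 0.0
    )
    try:
        section["alpha"] = phasing.compute_alpha(results)
    except ValueError:
        section["alpha"] = None
    section["sex_bias"] = phasing.sex_bias_tests(
        results, shared_ids, cpg_ids if cpg_ids else None
    )
    return section


def landscape_stage(
    unique_dnms: Sequence[DnmCandidate],
    reference: dict[str, str],
    blacklist: set[str],
    transcripts: Optional[Sequence[Transcript]] = None,
    map_df: Optional[pd.DataFrame] = None,
    callable_fraction: float = 1.0,
    window_size: int = landscape.WINDOW_SIZE,
    window_step: int = landscape.WINDOW_STEP,
) -> dict:
    """Sliding-window table plus correlations, regressions and mediation."""
    chrom_lengths = {
        c: len(s) for c, s in reference.items() if c not in blacklist
    }
    table = landscape.build_windows(
        chrom_lengths,
        [(d.chrom, d.pos) for d in unique_dnms],
        reference=reference,
        transcripts=transcripts,
        map_df=map_df,
        callable_fraction=callable_fraction,
        window_size=window_size,
        window_step=window_step,
    )
    land: dict = {"windows": table}
    for xvar in ("rec_rate", "cpg_density", "gene_density"):
        if table[xvar].notna().sum() >= 3:
            try:
                land[f"corr_{xvar}"] = landscape.correlate_windows(
                    table, xvar, "dnm_count"
                )
                land[f"poisson_{xvar}"] = (
                    landscape.poisson_window_regression(table, xvar)
                )
            except ValueError as exc:
                land[f"corr_{xvar}"] = None
                log.info("landscape %s: %s", xvar, exc)
    if (table["rec_rate"].notna().sum() >= 10
            and table["cpg_density"].notna().sum() >= 10):
        try:
            land["mediation"] = landscape.mediation_path(table)
        except ValueError as exc:
            land["mediation"] = None
            log.info("mediation: %s", exc)
    return land


def summarize(bundle: dict) -> dict:
    """Compact JSON-ready summary of a run."""
    s: dict = {}
    if bundle.get("rates"):
        pooled = bundle["rates"]["pooled_zero_inflated"]
        per_trio = bundle["rates"]["per_trio_mean"]
        s["mu_pooled"] = pooled.mu
        s["mu_per_trio_mean"] = per_trio.mu
        s["mu_ci"] = [per_trio.ci_low, per_trio.ci_high]
        s["n_dnm_curated"] = pooled.n_dnm
        s["sum_callable_bp"] = pooled.sum_cs
        s["mean_fnr"] = bundle["mean_fnr"]
        s["yearly_rate"] = bundle.get("yearly_rate")
    if bundle.get("validation"):
        s["fdr"] = bundle["validation"].fdr
    sharing = bundle.get("sharing")
    if sharing:
        s["n_unique_dnm"] = sharing.n_unique
        s["shared_percentage"] = sharing.shared_percentage
    spec = bundle.get("spectrum")
    if spec:
        s["ts_tv"] = spec.get("ts_tv")
        s["spectrum"] = spec["spectrum"].counts
        if spec.get("sw_bias"):
            s["sw_chi2"] = spec["sw_bias"].statistic
            s["sw_p"] = spec["sw_bias"].p_value
        s["n_cgi"] = len(spec.get("cgi", []))
    ph = bundle.get("phasing")
    if ph:
        s["phaseable_fraction"] = ph["phaseable_fraction"]
        if ph.get("alpha"):
            s["alpha"] = ph["alpha"].alpha
            s["paternal_fraction"] = ph["alpha"].paternal_fraction
    land = bundle.get("landscape")
    if land:
        for key in ("corr_rec_rate", "corr_cpg_density", "corr_gene_density"):
            res = land.get(key)
            if res is not None:
                s[key] = {"r": res.r, "p": res.p_value}
    s["funnel"] = bundle.get("funnel")
    return _jsonable(s)


# ---------------------------------------------------------------------------
# File-driven wrapper and output writing
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Read the configured inputs, run the analysis, write the output set."""
    trios = read_pedigree(config.pedigree)
    stats: dict = {}
    records = list(read_vcf(config.vcf, stats=stats))
    vcf_samples = set(stats.get("samples", []))
    missing = [
        m for t in trios for m in t.members if m not in vcf_samples
    ]
    if missing:
        raise ValueError(
            f"pedigree samples missing from VCF: {sorted(set(missing))}"
        )
    survey = (list(read_vcf(config.survey, include_monomorphic=True))
              if config.survey else None)
    evidence = read_read_evidence(config.evidence) if config.evidence else None
    reference = read_fasta(config.fasta) if config.fasta else None
    transcripts = read_gff3(config.gff3) if config.gff3 else None
    map_df = read_linkage_map(config.linkage_map) if config.linkage_map else None
    repeats = read_bed(config.repeats_bed) if config.repeats_bed else None
    bundle = run_analysis(
        records, trios, config.filters,
        survey=survey, evidence=evidence, reference=reference,
        transcripts=transcripts, map_df=map_df, repeats=repeats,
        window_size=config.window_size, window_step=config.window_step,
        generation_time=config.generation_time, seed=config.seed,
    )
    write_bundle(bundle, config.out_dir)
    return bundle


def read_candidates(path: str | Path, trios: Sequence[Trio]) -> list[DnmCandidate]:
    """Rehydrate a candidates TSV (as written by ``candidates_frame``)."""
    by_child = {t.child: t for t in trios}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for r in df.itertuples():
        trio = by_child.get(r.child)
        if trio is None:
            raise ValueError(f"candidate child {r.child!r} not in pedigree")
        cand = DnmCandidate(trio=trio, chrom=r.chrom, pos=int(r.pos),
                            ref=r.ref, alt=r.alt)
        for item in str(r.filter_trail).split(";"):
            if "=" in item:
                name, verdict = item.rsplit("=", 1)
                cand.filter_trail.append((name, verdict == "pass"))
        cand.validation = r.validation or None
        cand.shared_group = r.shared_group or None
        cand.origin = r.origin
        cand.context = r.context or None
        out.append(cand)
    return out


def candidates_frame(candidates: Sequence[DnmCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "family": c.trio.family, "child": c.trio.child,
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "filters_passed": c.passed_filters,
            "filter_trail": ";".join(
                f"{name}={'pass' if ok else 'fail'}" for name, ok in c.filter_trail
            ),
            "validation": c.validation or "",
            "shared_group": c.shared_group or "",
            "origin": c.origin, "context": c.context or "",
        })
    return pd.DataFrame(rows)


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates_frame(bundle["candidates"]).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    if bundle.get("rates"):
        rows = []
        for name, est in bundle["rates"].items():
            rows.append({
                "method": name, "mu": est.mu, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "n_dnm": est.n_dnm,
                "sum_cs": est.sum_cs, "fdr": est.fdr, "fnr": est.fnr,
            })
        pd.DataFrame(rows).to_csv(out / "rates.tsv", sep="\t", index=False)
    spec = bundle.get("spectrum")
    if spec:
        pd.DataFrame(
            sorted(spec["spectrum"].counts.items()),
            columns=["class", "count"],
        ).to_csv(out / "spectrum.tsv", sep="\t", index=False)
        write_bed(
            [(i.chrom, i.start, i.end, i.cgi_class or ".",
              f"{i.gc_fraction:.3f}", f"{i.obs_exp_cpg:.3f}")
             for i in spec.get("cgi", [])],
            out / "cgi.bed",
        )
    land = bundle.get("landscape")
    if land is not None and land.get("windows") is not None:
        land["windows"].to_csv(out / "windows.tsv", sep="\t", index=False)
    ph = bundle.get("phasing")
    if ph:
        pd.DataFrame([
            {"dnm": r.dnm_id, "origin": r.origin,
             "paternal_fragments": r.paternal_fragments,
             "maternal_fragments": r.maternal_fragments,
             "informative_sites": r.informative_sites_used}
            for r in ph["results"]
        ]).to_csv(out / "phased.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
        fh.write("\n")
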