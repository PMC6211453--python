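"""End-to-end orchestration: files in, peak BED and model JSON out."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import coverage_model as cm
from . import diag_model as dm
from . import nhmm, readprep

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and thresholds of a peak-calling run."""

    clip_paths: list[str]
    background_paths: list[str]
    annotation: str
    out_dir: str
    mirna_path: str | None = None
    peak_penalty: float = 0.0
    max_mismatches: int = 2
    snp_min_reads: int = 20
    snp_min_frac: float = 0.2
    k_components: int = 10
    min_iter: int = 5
    max_iter: int = 10
    alpha_bonferroni: float = 0.05
    min_mapq: int = 0
    checkpoints: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clip_paths:
            raise ValueError("at least one CLIP library is required")


def model_to_dict(model: nhmm.FittedModel) -> dict:
    g = model.glm
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "glm": {
            "beta0": g.beta0,
            "beta_gene": g.beta_gene.tolist(),
            "beta_enrich": g.beta_enrich,
            "libsize": g.libsize.tolist(),
            "dispersion": g.dispersion,
            "gene_ids": list(g.gene_ids),
            "diagnostics": g.diagnostics,
        },
        "dmm": {
            name: {
                "model_class": p.model_class,
                "K": p.K,
                "weights": p.weights.tolist(),
                "alphas": p.alphas.tolist(),
            }
            for name, p in (
                ("peak", model.dmm_peak),
                ("background", model.dmm_background),
            )
        },
        "transitions": {"w0": model.transitions.w0, "w1": model.transitions.w1},
        "loglik_trace": list(model.loglik_trace),
    }


def model_from_dict(d: dict) -> nhmm.FittedModel:
    g = d["glm"]
    glm = cm.GLMParams(
        beta0=g["beta0"],
        beta_gene=np.array(g["beta_gene"]),
        beta_enrich=g["beta_enrich"],
        libsize=np.array(g["libsize"]),
        dispersion=g["dispersion"],
        gene_ids=tuple(g["gene_ids"]),
        diagnostics=g.get("diagnostics", {}),
    )
    dmms = {
        name: dm.DMMParams(
            model_class=p["model_class"],
            K=p["K"],
            weights=np.array(p["weights"]),
            alphas=np.array(p["alphas"]),
        )
        for name, p in d["dmm"].items()
    }
    t = d["transitions"]
    return nhmm.FittedModel(
        glm=glm,
        dmm_peak=dmms["peak"],
        dmm_background=dmms["background"],
        transitions=nhmm.TransitionParams(t["w0"], t["w1"]),
        loglik_trace=list(d.get("loglik_trace", [])),
    )


def write_peaks_bed(peaks: list[nhmm.PeakCall], path: str) -> None:
    """BED6+3: name is gene:index, score is the site LLR, then summit offset,
    p and Bonferroni-adjusted p."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            fh.write(
                "\t".join(
                    [
                        pk.chrom,
                        str(pk.start),
                        str(pk.end),
                        f"{pk.gene_id}:{i}",
                        f"{pk.site_score:.4f}",
                        pk.strand,
                        str(pk.summit - pk.start),
                        f"{pk.p_value:.3e}",
                        f"{pk.p_adj:.3e}",
                    ]
                )
                + "\n"
            )


def run_pipeline(config: RunConfig):
    """Full run: load, filter, fit, decode, and write peaks/model/report.

    Deterministic for a fixed seed.  Returns (peaks, model, tensors, genes).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    genes = readprep.load_genes_gtf(config.annotation, config.mirna_path)
    if not genes:
        raise ValueError(f"no genes loaded from {config.annotation}")
    roles = ["CLIP"] * len(config.clip_paths) + ["background"] * len(
        config.background_paths
    )
    reads = []
    for path in list(config.clip_paths) + list(config.background_paths):
        if not os.path.exists(path):
            raise FileNotFoundError(f"alignment file not found: {path}")
        reads.append(readprep.load_reads_sam(path, genes, config.min_mapq))
    tensors = readprep.build_tensors(
        reads,
        genes,
        roles,
        mask_snps=bool(config.background_paths),
        max_mismatches=config.max_mismatches,
        snp_min_reads=config.snp_min_reads,
        snp_min_frac=config.snp_min_frac,
    )

    fit_config = nhmm.FitConfig(
        k_components=config.k_components,
        min_iter=config.min_iter,
        max_iter=config.max_iter,
        seed=config.seed,
        peak_penalty=config.peak_penalty,
        alpha_bonferroni=config.alpha_bonferroni,
    )
    checkpoint = None
    if config.checkpoints:
        ckpt_dir = os.path.join(config.out_dir, "checkpoints")
        os.makedirs(ckpt_dir, exist_ok=True)

        def checkpoint(iteration, model):
            with open(
                os.path.join(ckpt_dir, f"model_iter{iteration:02d}.json"), "w"
            ) as fh:
                json.dump(model_to_dict(model), fh, indent=1)

    model = nhmm.em_fit(tensors, fit_config, checkpoint=checkpoint)
    peaks = nhmm.call_peaks(tensors, genes, model)

    write_peaks_bed(peaks, os.path.join(config.out_dir, "peaks.bed"))
    with open(os.path.join(config.out_dir, "model.json"), "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
    with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
        fh.write("clippeaks run report\n")
        fh.write(f"genes: {len(genes)}\n")
        fh.write(f"libraries: {roles}\n")
        fh.write(
            "library sizes (log): "
            + " ".join(f"{v:.3f}" for v in model.glm.libsize)
            + "\n"
        )
        fh.write(f"dispersion c: {model.glm.dispersion:.4f}\n")
        fh.write(f"enrichment beta: {model.glm.beta_enrich:.4f}\n")
        fh.write(
            "EM log-evidence trace: "
            + " ".join(f"{v:.2f}" for v in model.loglik_trace)
            + "\n"
        )
        fh.write(f"candidate->significant peaks: {len(peaks)}\n")
    return peaks, model, tensors, genes
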