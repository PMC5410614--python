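"""End-to-end pipeline driver with a reproducibility manifest.

Stage order mirrors a standard SSR association-mapping workflow:
diversity → structure (admixture + ΔK) → tree/PCoA → AMOVA → phenotype
statistics → LD → MLM scans → favorable-allele mining → cross proposals.
Each stage draws its randomness from a substream of the single run seed, so
a rerun with the same inputs and seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np

from . import __version__, panel_io
from .errors import MilletMapError

log = logging.getLogger("milletmap")


def _substream(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    *,
    genotypes_path: str,
    phenotypes_path: str,
    out_dir: str,
    kmin: int = 1,
    kmax: int = 6,
    restarts: int = 5,
    max_iter: int = 2000,
    n_perm: int = 200,
    min_effect: float = 4.0,
    min_class_size: int = 3,
    seed: int = 0,
) -> dict:
    """Run every stage; returns (and writes) the manifest dict.

    Any stage failure aborts with the failing stage named; partial outputs
    written so far are flagged in the manifest on disk.
    """
    from . import association as assoc
    from . import diversity as dv
    from . import phenotype_stats as phs
    from . import population_structure as ps
    from .allele_mining import (
        AlleleEffect,
        CrossProposal,
        allele_effects,
        favorable_alleles,
        genotype_allele_inventory,
        propose_crosses,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "kmin": kmin,
            "kmax": kmax,
            "restarts": restarts,
            "max_iter": max_iter,
            "n_perm": n_perm,
            "min_effect": min_effect,
            "min_class_size": min_class_size,
        },
        "stages": {},
        "complete": False,
    }
    manifest_path = out / "manifest.json"

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.time()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    manifest["failed_stage"] = name
                    manifest_path.write_text(json.dumps(manifest, indent=1))
                    if isinstance(exc, MilletMapError):
                        raise MilletMapError(f"stage {name!r} failed: {exc}") from exc
                    return False
                manifest["stages"][name] = {
                    "seconds": round(time.time() - self_inner.t0, 2)
                }
                log.info(
                    "stage %s: done (%.1fs)", name, time.time() - self_inner.t0
                )
                return False

        return _Timer()

    with stage("load"):
        panel = panel_io.read_genotypes(genotypes_path)
        try:
            pheno = panel_io.read_phenotypes(phenotypes_path)
        except FileNotFoundError as exc:
            raise MilletMapError(f"phenotype file unreadable: {exc}") from exc
        pheno.check_against_panel(panel)

    with stage("diversity"):
        summaries = dv.allele_summary(panel)
        dv.summary_table(summaries).to_csv(
            out / "diversity.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["stages"].setdefault("diversity", {})
        means = dv.panel_means(summaries)

    with stage("structure"):
        runs_by_k = {
            K: ps.fit_admixture(
                panel,
                K,
                restarts=restarts,
                max_iter=max_iter,
                seed=_substream(seed, "structure"),
            )
            for K in range(kmin, kmax + 1)
        }
        evanno = ps.evanno_delta_k(runs_by_k)
        evanno.to_csv(out / "evanno.tsv", sep="\t", index=False, float_format="%.6g")
        best_k = ps.best_k(evanno)
        best = runs_by_k[best_k][0]
        panel_io.write_q_matrix(best.Q.line_ids, best.Q.q, out / "q_matrix.csv")
        assignment = ps.assign_subpopulations(best.Q)

    with stage("tree_pcoa"):
        dist = ps.nei_distance(panel)
        panel_io.write_newick(ps.nj_tree(dist), out / "nj_tree.nwk")
        coords, explained = ps.pcoa(dist, n_axes=3)
        coords.to_csv(out / "pcoa.csv", float_format="%.6g")

    with stage("amova"):
        am = ps.amova(
            panel, assignment, n_perm=max(n_perm, 99), seed=_substream(seed, "amova")
        )
        am.table().to_csv(out / "amova.tsv", sep="\t", index=False, float_format="%.6g")

    with stage("kinship"):
        kin = ps.kinship(panel)
        panel_io.write_kinship(kin.line_ids, kin.k, out / "kinship.csv")

    with stage("pheno_stats"):
        vc = {}
        for trait in panel_io.TRAITS:
            phs.descriptive_table(pheno, trait).to_csv(
                out / f"descriptives_{trait}.tsv", sep="\t", float_format="%.4f"
            )
            vc[trait] = phs.combined_anova(pheno, trait)

    with stage("ld"):
        ldt = assoc.ld_matrix(panel, n_perm=n_perm, seed=_substream(seed, "ld"))
        ldt.to_csv(out / "ld.tsv", sep="\t", index=False, float_format="%.6g")

    with stage("gwas"):
        thr, _ = assoc.bonferroni_threshold(panel.n_markers)
        records = []
        for trait in panel_io.TRAITS:
            coll = phs.build_datasets(pheno, trait)
            for name in coll.names():
                records += assoc.mlm_scan(
                    coll[name],
                    panel,
                    best.Q,
                    kin,
                    trait=trait,
                    dataset_name=name,
                    min_class_size=min_class_size,
                )
        panel_io.write_report(records, out / "mta.tsv", kind=assoc.MTARecord)
        freq = assoc.mta_frequency(records, thr)
        freq.to_csv(out / "mta_frequency.tsv", sep="\t", index=False)

    with stage("mining"):
        sig = {
            t: sorted(
                {r.marker_id for r in records if r.trait == t and r.p < thr}
            )
            for t in panel_io.TRAITS
        }
        fav = []
        all_effects = []
        for trait, mks in sig.items():
            if not mks:
                continue
            y = phs.build_datasets(pheno, trait)["GM"]
            eff = allele_effects(panel, y, mks, trait=trait, dataset_name="GM")
            all_effects += eff
            fav += favorable_alleles(
                eff, min_effect=min_effect, one_per_marker=True, min_carriers=5
            )
        panel_io.write_report(all_effects, out / "allele_effects.tsv", kind=AlleleEffect)

    with stage("crosses"):
        if fav:
            inv = genotype_allele_inventory(panel, fav)
            crosses = propose_crosses(inv, top_n=10)
        else:
            crosses = []
        panel_io.write_report(crosses, out / "crosses.tsv", kind=CrossProposal)

    manifest["complete"] = True
    manifest["summary"] = {
        "n_lines": panel.n_lines,
        "n_markers": panel.n_markers,
        "mean_gene_diversity": means["mean_gene_diversity"],
        "best_K": best_k,
        "fst": am.f_st,
        "pct_among_subpops": am.pct_among,
        "h2_multi": {t: phs.heritability(v, "multi") for t, v in vc.items()},
        "n_significant_mta": int(sum(r.p < thr for r in records)),
        "n_favorable_alleles": len(fav),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
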