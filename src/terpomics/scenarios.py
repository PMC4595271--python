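"""Planted-truth simulation scenarios for calibration and recovery studies.

These builders assemble small, seeded datasets with known ground truth:

* :func:`make_integration_scenario` runs the full quantification path
  (counts -> multi-read rescue -> RPKM -> condition means -> DE calls)
  on a reduced gene universe in which one gene is planted with strong
  correlations (r = 0.9 by default) to three bound-form compounds and a
  regional fold-change at the final stage.  Candidate nomination should
  recover that gene and almost never nominate the null genes.

* :func:`make_anchor_tf_scenario` builds per-condition expression
  profiles around two anchor genes that share a latent ripening
  trajectory: transcription factors planted to co-express with both
  anchors (positively or negatively), decoy factors correlated with only
  one anchor (built by an exact rotation in the anchor plane, so their
  correlations sit at known values on either side of the admission
  threshold), background factors, and ripening-associated genes tied to
  the admitted factors.  The anchored-network construction should
  recover exactly the planted factor layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import Comparison, assign_multireads, call_degs, rpkm_matrix
from .integration import correlation_table, nominate_candidates
from .synthetic import DesignConfig, PlantedEffect, PlantedPartner, generate_dataset

PLANTED_GENE = "UGT_000"
PLANTED_COMPOUNDS = ("bound_cmpd_00", "bound_cmpd_01", "bound_cmpd_02")


def _condition_log_means(
    matrix: pd.DataFrame, library_meta: pd.DataFrame, pseudo: float = 1.0
) -> pd.DataFrame:
    """log2(RPKM + pseudo) averaged into one column per condition cell."""
    log = np.log2(matrix + pseudo)
    cols = {}
    for (region, year, stage), sub in library_meta.groupby(
        ["region", "year", "stage"], sort=True
    ):
        cols[f"{region}|{year}|{stage}"] = log[sub["library"]].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class IntegrationScenario:
    candidates: pd.DataFrame
    planted_gene: str
    null_genes: list[str]
    correlations: pd.DataFrame
    degs: pd.DataFrame


def make_integration_scenario(
    seed: int,
    *,
    planted_r: float = 0.9,
    region_multiplier: float = 4.0,
    r_min: float = 0.8,
) -> IntegrationScenario:
    """Planted gene-metabolite recovery on a reduced gene universe."""
    # the background universe is kept large enough that no single gene
    # dominates a library: with very few genes a strong planted effect
    # distorts every other gene's fraction (a compositional artifact the
    # full-transcriptome study does not have)
    config = DesignConfig(
        n_transcripts={"UGT": 8, "TF": 6, "TPS-b": 16, "other": 70},
        n_compounds={"free": 2, "bound": 3},
        total_reads_per_library=2e5,
        n_multiread_groups=5,
        seed=seed,
    )
    effect = PlantedEffect(
        target=PLANTED_GENE,
        archetype="increasing",
        region_multiplier=region_multiplier,
        partners=tuple(
            PlantedPartner(c, planted_r, kind="metabolite")
            for c in PLANTED_COMPOUNDS
        ),
        noise_sd=0.05,
    )
    bundle = generate_dataset(config, [effect])

    groups_by_lib = {
        lib: [
            (row["candidates"].split(";"), row["multiplicity"])
            for _, row in sub.iterrows()
        ]
        for lib, sub in bundle.multiread_groups.groupby("library")
    }
    assigned = {}
    for lib in bundle.unique_counts.columns:
        assigned[lib] = assign_multireads(
            bundle.unique_counts[lib].to_dict(), groups_by_lib.get(lib, [])
        )
    counts = pd.DataFrame(assigned).reindex(bundle.unique_counts.index)
    lengths = bundle.transcripts.set_index("transcript")["length_nt"]
    totals = bundle.library_meta.set_index("library")["total_mapped"]
    rpkms = rpkm_matrix(counts, lengths, totals)

    expr = _condition_log_means(rpkms, bundle.library_meta)
    met_means = (
        bundle.metabolites.groupby(["compound", "region", "year", "stage"])[
            "concentration_ug_l"
        ]
        .mean()
        .reset_index()
    )
    met_means["cell"] = (
        met_means["region"].astype(str)
        + "|"
        + met_means["year"].astype(str)
        + "|"
        + met_means["stage"].astype(str)
    )
    met = np.log2(
        met_means.pivot(index="compound", columns="cell", values="concentration_ug_l")
    )[expr.columns]

    corr = correlation_table(expr, met, mode="instantaneous")

    final = config.stages[-1]
    cond = {}
    for _, row in bundle.library_meta.iterrows():
        cond[row["library"]] = f"{row['region']}|{row['year']}|{row['stage']}"
    comparisons = [
        Comparison(
            label=f"{config.regions[0]}-vs-{config.regions[1]}@{final}/{year}",
            condition_a=f"{config.regions[0]}|{year}|{final}",
            condition_b=f"{config.regions[1]}|{year}|{final}",
        )
        for year in config.years
    ]
    degs = call_degs(counts, cond, comparisons)

    candidates = nominate_candidates(corr, degs, r_min=r_min)
    null_genes = [g for g in rpkms.index if g != PLANTED_GENE]
    return IntegrationScenario(
        candidates=candidates,
        planted_gene=PLANTED_GENE,
        null_genes=null_genes,
        correlations=corr,
        degs=degs,
    )


@dataclass
class AnchorTFScenario:
    anchors: pd.DataFrame
    tfs: pd.DataFrame
    ripening: pd.DataFrame
    true_tfs: set[str]
    true_tf_signs: dict[str, str]
    true_ripening: set[str]


def make_anchor_tf_scenario(
    seed: int,
    *,
    n_background_tfs: int = 10,
    noise_sd: float = 0.05,
    n_cells: int = 16,
) -> AnchorTFScenario:
    """Planted anchor-TF-ripening structure on per-condition profiles.

    The two anchors share a latent trajectory z; a second in-sample
    orthogonalized direction v lets single-anchor decoys be placed at
    exact correlation coordinates (about 0.77 to one anchor, 0.96 to the
    other) so that the all-anchors admission rule excludes them with a
    wide, seed-independent margin.
    """
    rng = np.random.default_rng(seed)
    cells = [f"cell_{i:02d}" for i in range(n_cells)]

    base = np.repeat(np.linspace(0.0, 3.0, 4), max(1, n_cells // 4))[:n_cells]
    z = base + rng.normal(0.0, 0.5, n_cells)
    z = (z - z.mean()) / z.std()
    v_raw = rng.standard_normal(n_cells)
    v_raw = v_raw - (v_raw @ z) / (z @ z) * z  # in-sample orthogonal to z
    v = (v_raw - v_raw.mean()) / v_raw.std()

    mix = (z + 0.45 * v) / np.sqrt(1.0 + 0.45**2)
    anchors = pd.DataFrame(
        {
            "anchor_HDR": 5.0 + z + rng.normal(0.0, 0.02, n_cells),
            "anchor_GT14": 4.0 + mix + rng.normal(0.0, 0.02, n_cells),
        }
    ).T
    anchors.columns = cells

    cos40, sin40 = np.cos(np.deg2rad(40.0)), np.sin(np.deg2rad(40.0))
    tf_rows = {}
    true_signs = {}
    for name in ("TF_pos_00",):
        tf_rows[name] = 3.0 + z + rng.normal(0.0, noise_sd, n_cells)
        true_signs[name] = "positive"
    for name in ("TF_neg_00", "TF_neg_01"):
        tf_rows[name] = 3.0 - z + rng.normal(0.0, noise_sd, n_cells)
        true_signs[name] = "negative"
    for name in ("TF_oneanchor_00", "TF_oneanchor_01"):
        tf_rows[name] = (
            3.0 + cos40 * z + sin40 * v + rng.normal(0.0, 0.02, n_cells)
        )
    for i in range(n_background_tfs):
        tf_rows[f"TF_bg_{i:02d}"] = 3.0 + rng.standard_normal(n_cells)
    tfs = pd.DataFrame(tf_rows).T
    tfs.columns = cells

    rip_rows = {}
    true_rip = set()
    for i, sign in enumerate((1.0, 1.0, -1.0)):
        name = f"rip_{i:02d}"
        rip_rows[name] = 2.0 + sign * z + rng.normal(0.0, noise_sd, n_cells)
        true_rip.add(name)
    for i in range(2):
        rip_rows[f"rip_bg_{i:02d}"] = 2.0 + rng.standard_normal(n_cells)
    ripening = pd.DataFrame(rip_rows).T
    ripening.columns = cells

    return AnchorTFScenario(
        anchors=anchors,
        tfs=tfs,
        ripening=ripening,
        true_tfs=set(true_signs),
        true_tf_signs=true_signs,
        true_ripening=true_rip,
    )
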