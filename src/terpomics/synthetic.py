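"""Seeded synthetic datasets with the study's statistical structure.

The generator emulates a two-region x two-year x four-stage grape berry
design: 24 RNA-seq libraries (one library per region-year at the
pea-size and intermediate-Brix stages, two at veraison onset and at
harvest) and 32 metabolite samples (two biological repeats per condition
cell).  Every downstream stage of the pipeline -- multi-read rescue,
RPKM, DE testing, trend clustering, gene-metabolite correlation,
co-expression networks, qPCR validation and climate summaries -- can be
exercised on its output without any external download.

Model
-----
Each transcript (and compound) follows a log2-scale latent profile over
the 16 condition cells: a per-feature baseline, an archetype stage
trajectory (increasing / decreasing / peaked / stable), a small year
effect and cell-level noise.  Planted effects override the archetype,
add a first-region multiplier ramped toward the final stage (the
"higher in CL at harvest" pattern), and attach correlation partners:
a partner's latent is r * z + sqrt(1 - r^2) * g for the standardized
target latent z and independent Gaussian g, so the realized sample
correlation is close to, but honestly not exactly, the requested r.

Read counts are negative-binomial around the latent means (the standard
overdispersed model for RNA-seq counts); a configurable share of counts
is diverted into multi-read groups so the proportional rescue step has
something to do, with exact count conservation.  Metabolite
concentrations are log-normal in micrograms per litre, with the bound
form more abundant than the free form by a configurable factor.

The same seed always regenerates a byte-identical serialized bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import climate as climate_mod

ARCHETYPES = ("increasing", "decreasing", "peaked", "stable")

_DEFAULT_LIBS_PER_CELL = {"E-L31": 1, "E-L35": 2, "E-L36": 1, "E-L38": 2}
_DEFAULT_N_TRANSCRIPTS = {
    "MEP": 7,
    "MVA": 6,
    "TPS-a": 20,
    "TPS-b": 25,
    "TPS-g": 21,
    "UGT": 147,
    "TF": 725,
    "ripening": 20,
    "other": 100,
}
_DEFAULT_N_COMPOUNDS = {"free": 25, "bound": 25}


@dataclass(frozen=True)
class PlantedPartner:
    """A correlation partner of a planted effect target."""

    partner: str
    r: float
    kind: str = "metabolite"  # "metabolite" or "gene"

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise ValueError(f"impossible correlation request |r|>1: {self.r}")
        if self.kind not in ("metabolite", "gene"):
            raise ValueError(f"unknown partner kind: {self.kind!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """A target feature with archetype, region effect and planted partners."""

    target: str
    archetype: str = "increasing"
    region_multiplier: float = 1.0
    partners: tuple[PlantedPartner, ...] = ()
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if self.region_multiplier <= 0:
            raise ValueError("region multiplier must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class DesignConfig:
    """The sampling design and generator knobs; the seed fixes everything."""

    regions: tuple[str, ...] = ("CL", "GT")
    years: tuple[int, ...] = (2010, 2011)
    stages: tuple[str, ...] = ("E-L31", "E-L35", "E-L36", "E-L38")
    libs_per_cell: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_LIBS_PER_CELL)
    )
    metab_reps_per_cell: int = 2
    n_transcripts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_TRANSCRIPTS)
    )
    n_compounds: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_COMPOUNDS)
    )
    total_reads_per_library: float = 1e6
    nb_dispersion: float = 0.05
    profile_noise_sd: float = 0.1
    year_effect_sd: float = 0.15
    metab_replicate_noise_sd: float = 0.15
    bound_over_free_factor: float = 3.0
    n_multiread_groups: int = 30
    multiread_share: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stages must be unique and ordered")
        missing = [s for s in self.stages if s not in self.libs_per_cell]
        if missing:
            raise ValueError(f"libs_per_cell missing stages: {missing}")
        if self.metab_reps_per_cell < 1:
            raise ValueError("metab_reps_per_cell must be >= 1")
        if self.total_reads_per_library <= 0:
            raise ValueError("total_reads_per_library must be positive")

    @property
    def cells(self) -> list[tuple[str, int, str]]:
        return [
            (region, year, stage)
            for region in self.regions
            for year in self.years
            for stage in self.stages
        ]

    @property
    def n_libraries(self) -> int:
        per_region_year = sum(self.libs_per_cell[s] for s in self.stages)
        return per_region_year * len(self.regions) * len(self.years)

    @property
    def n_metabolite_samples(self) -> int:
        return len(self.cells) * self.metab_reps_per_cell


@dataclass
class Bundle:
    """A complete synthetic dataset plus its provenance manifest."""

    transcripts: pd.DataFrame
    library_meta: pd.DataFrame
    unique_counts: pd.DataFrame
    multiread_groups: pd.DataFrame
    metabolites: pd.DataFrame
    thresholds: pd.DataFrame
    qpcr: pd.DataFrame
    climate: pd.DataFrame
    manifest: dict
    #: ground-truth log2 latent cell profiles of planted targets/partners
    planted_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    _FILES = {
        "transcripts": ("transcripts.tsv", "\t"),
        "library_meta": ("library_meta.tsv", "\t"),
        "unique_counts": ("unique_counts.tsv", "\t"),
        "multiread_groups": ("multiread_groups.tsv", "\t"),
        "metabolites": ("metabolites.csv", ","),
        "thresholds": ("thresholds.csv", ","),
        "qpcr": ("qpcr.csv", ","),
        "climate": ("climate.csv", ","),
        "planted_truth": ("planted_truth.tsv", "\t"),
    }
    _INDEXED = ("unique_counts", "planted_truth")

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        hashes: dict[str, str] = {}
        for attr, (fname, sep) in self._FILES.items():
            df: pd.DataFrame = getattr(self, attr)
            path = out_dir / fname
            df.to_csv(path, sep=sep, index=attr in self._INDEXED,
                      float_format="%.10g")
            paths[attr] = path
            hashes[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = dict(self.manifest)
        manifest["files"] = hashes
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = mpath
        return paths

    @classmethod
    def read(cls, in_dir) -> "Bundle":
        in_dir = Path(in_dir)
        kwargs = {}
        for attr, (fname, sep) in cls._FILES.items():
            path = in_dir / fname
            if attr == "planted_truth" and not path.exists():
                kwargs[attr] = pd.DataFrame()
                continue
            index_col = 0 if attr in cls._INDEXED else None
            kwargs[attr] = pd.read_csv(path, sep=sep, index_col=index_col)
        mpath = in_dir / "manifest.json"
        manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
        return cls(manifest=manifest, **kwargs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

#: log2 stage trajectories, evaluated on normalized stage positions
def _trajectory(archetype: str, n_stages: int, amplitude: float = 3.0) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n_stages)
    if archetype == "increasing":
        return amplitude * x
    if archetype == "decreasing":
        return amplitude * (1.0 - x)
    if archetype == "peaked":
        return amplitude * np.exp(-(((x - 0.45) / 0.22) ** 2))
    if archetype == "stable":
        return np.zeros(n_stages)
    raise ValueError(f"unknown archetype {archetype!r}")


_CATEGORY_ARCHETYPE_WEIGHTS = {
    # terpenes accumulate after veraison, so pathway genes skew increasing;
    # TPS subfamilies are split young-berry vs ripe-berry; TFs are mixed
    "MEP": (0.5, 0.2, 0.1, 0.2),
    "MVA": (0.2, 0.5, 0.1, 0.2),
    "TPS-a": (0.3, 0.4, 0.1, 0.2),
    "TPS-b": (0.2, 0.5, 0.1, 0.2),
    "TPS-g": (0.3, 0.4, 0.1, 0.2),
    "UGT": (0.25, 0.25, 0.2, 0.3),
    "TF": (0.3, 0.3, 0.2, 0.2),
    "ripening": (0.7, 0.1, 0.1, 0.1),
    "other": (0.15, 0.15, 0.1, 0.6),
}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def correlated_profile(
    rng: np.random.Generator,
    target: np.ndarray,
    r: float,
    *,
    scale: float | None = None,
    location: float = 0.0,
) -> np.ndarray:
    """A latent profile with expected correlation r to ``target``.

    Built as r*z + sqrt(1-r^2)*g on the standardized target z with fresh
    Gaussian g; the realized sample correlation fluctuates around r.
    """
    if abs(r) > 1:
        raise ValueError(f"impossible correlation request |r|>1: {r}")
    z = _standardize(np.asarray(target, dtype=float))
    g = rng.standard_normal(z.shape)
    mix = r * z + np.sqrt(1.0 - r * r) * g
    if scale is None:
        scale = float(np.std(target)) or 1.0
    return location + scale * mix


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    means = np.clip(means, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(means)
    size = 1.0 / dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p)


def generate_dataset(
    config: DesignConfig, effects: Sequence[PlantedEffect] = ()
) -> Bundle:
    """Generate a complete seeded bundle under the configured design."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = config.cells
    n_cells = len(cells)
    n_stages = len(config.stages)
    stage_rank = {s: i for i, s in enumerate(config.stages)}
    ramp = np.array([stage_rank[s] / max(1, n_stages - 1) for _, _, s in cells])
    is_first_region = np.array([r == config.regions[0] for r, _, _ in cells])

    # --- transcript annotation -------------------------------------------
    ids, categories = [], []
    for cat in sorted(config.n_transcripts):
        for i in range(config.n_transcripts[cat]):
            ids.append(f"{cat}_{i:03d}")
            categories.append(cat)
    n_t = len(ids)
    lengths = rng.integers(600, 3001, n_t)
    transcripts = pd.DataFrame(
        {"transcript": ids, "length_nt": lengths, "category": categories}
    )
    id_index = {t: i for i, t in enumerate(ids)}

    # --- compound ids -----------------------------------------------------
    compound_ids, compound_forms = [], []
    for form in sorted(config.n_compounds):
        for i in range(config.n_compounds[form]):
            compound_ids.append(f"{form}_cmpd_{i:02d}")
            compound_forms.append(form)
    cmpd_index = {c: i for i, c in enumerate(compound_ids)}

    # --- validate effects -------------------------------------------------
    effect_by_target: dict[str, PlantedEffect] = {}
    for eff in effects:
        if eff.target not in id_index and eff.target not in cmpd_index:
            raise KeyError(f"effect target not among generated ids: {eff.target!r}")
        for p in eff.partners:
            pool = cmpd_index if p.kind == "metabolite" else id_index
            if p.partner not in pool:
                raise KeyError(
                    f"planted partner not among generated ids: {p.partner!r}"
                )
        effect_by_target[eff.target] = eff

    planted_ids = set(effect_by_target)
    for eff in effects:
        planted_ids.update(p.partner for p in eff.partners)

    # --- transcript latent profiles (log2 scale) --------------------------
    base = rng.normal(5.0, 1.5, n_t)
    trajs = {a: _trajectory(a, n_stages) for a in ARCHETYPES}
    arch_choice = np.empty(n_t, dtype=object)
    for i, cat in enumerate(categories):
        arch_choice[i] = rng.choice(
            ARCHETYPES, p=_CATEGORY_ARCHETYPE_WEIGHTS[cat]
        )
    year_effects = {
        (i, y): rng.normal(0.0, config.year_effect_sd)
        for i in range(n_t)
        for y in config.years
    }

    latent = np.empty((n_t, n_cells))
    for i, tid in enumerate(ids):
        eff = effect_by_target.get(tid)
        arch = eff.archetype if eff else arch_choice[i]
        noise_sd = eff.noise_sd if eff else config.profile_noise_sd
        traj = trajs[arch]
        stage_part = np.array([traj[stage_rank[s]] for _, _, s in cells])
        year_part = np.array([year_effects[(i, y)] for _, y, _ in cells])
        row = base[i] + stage_part + year_part + rng.normal(0.0, noise_sd, n_cells)
        if eff and eff.region_multiplier != 1.0:
            row = row + np.log2(eff.region_multiplier) * ramp * is_first_region
        latent[i] = row

    # --- compound latent profiles ----------------------------------------
    c_base = {
        "free": np.log2(20.0),
        "bound": np.log2(20.0 * config.bound_over_free_factor),
    }
    n_c = len(compound_ids)
    c_latent = np.empty((n_c, n_cells))
    for j, (cid, form) in enumerate(zip(compound_ids, compound_forms)):
        eff = effect_by_target.get(cid)
        arch = (
            eff.archetype
            if eff
            else rng.choice(ARCHETYPES, p=(0.55, 0.15, 0.15, 0.15))
        )
        noise_sd = eff.noise_sd if eff else config.profile_noise_sd
        traj = trajs[arch]
        stage_part = np.array([traj[stage_rank[s]] for _, _, s in cells])
        b = c_base.get(form, np.log2(20.0)) + rng.normal(0.0, 0.5)
        row = b + stage_part + rng.normal(0.0, noise_sd, n_cells)
        if eff and eff.region_multiplier != 1.0:
            row = row + np.log2(eff.region_multiplier) * ramp * is_first_region
        c_latent[j] = row

    # --- planted partners override their latents --------------------------
    for eff in effects:
        if eff.target in id_index:
            t_vec = latent[id_index[eff.target]]
        else:
            t_vec = c_latent[cmpd_index[eff.target]]
        for p in eff.partners:
            if p.kind == "metabolite":
                j = cmpd_index[p.partner]
                form = compound_forms[j]
                c_latent[j] = correlated_profile(
                    rng, t_vec, p.r, location=c_base.get(form, np.log2(20.0))
                ) + rng.normal(0.0, eff.noise_sd, n_cells)
            else:
                i = id_index[p.partner]
                latent[i] = correlated_profile(
                    rng, t_vec, p.r, location=base[i]
                ) + rng.normal(0.0, eff.noise_sd, n_cells)

    # --- library counts ---------------------------------------------------
    libraries = []
    for ci, (region, year, stage) in enumerate(cells):
        for rep in range(1, config.libs_per_cell[stage] + 1):
            libraries.append((f"{region}_{year}_{stage}_rep{rep}", ci, region,
                              year, stage, rep))
    weights = np.power(2.0, latent)
    counts = np.empty((n_t, len(libraries)), dtype=np.int64)
    for li, (_, ci, *_rest) in enumerate(libraries):
        frac = weights[:, ci] / weights[:, ci].sum()
        counts[:, li] = _nb_counts(
            rng, frac * config.total_reads_per_library, config.nb_dispersion
        )

    # --- divert a share into multi-read groups ----------------------------
    eligible = [
        i for i, tid in enumerate(ids) if tid not in planted_ids
    ]
    group_rows = []
    unique = counts.copy()
    by_cat: dict[str, list[int]] = {}
    for i in eligible:
        by_cat.setdefault(categories[i], []).append(i)
    candidate_cats = [c for c, members in sorted(by_cat.items()) if len(members) >= 2]
    n_groups = min(
        config.n_multiread_groups,
        sum(len(by_cat[c]) // 2 for c in candidate_cats),
    )
    used: set[int] = set()
    g = 0
    while g < n_groups and candidate_cats:
        cat = candidate_cats[g % len(candidate_cats)]
        pool = [i for i in by_cat[cat] if i not in used]
        if len(pool) < 2:
            candidate_cats.remove(cat)
            continue
        pair = rng.choice(len(pool), size=2, replace=False)
        members = [pool[pair[0]], pool[pair[1]]]
        used.update(members)
        for li, (lib, *_rest) in enumerate(libraries):
            moved = [
                int(rng.binomial(unique[m, li], config.multiread_share))
                for m in members
            ]
            multiplicity = int(sum(moved))
            for m, mv in zip(members, moved):
                unique[m, li] -= mv
            if multiplicity > 0:
                group_rows.append(
                    {
                        "library": lib,
                        "group_id": f"grp_{g:03d}",
                        "candidates": ";".join(ids[m] for m in members),
                        "multiplicity": multiplicity,
                    }
                )
        g += 1

    lib_ids = [lib for lib, *_ in libraries]
    unique_counts = pd.DataFrame(unique, index=pd.Index(ids, name="transcript"),
                                 columns=lib_ids)
    multiread_groups = pd.DataFrame(
        group_rows, columns=["library", "group_id", "candidates", "multiplicity"]
    )
    totals = counts.sum(axis=0)
    library_meta = pd.DataFrame(
        {
            "library": lib_ids,
            "region": [r for _, _, r, _, _, _ in libraries],
            "year": [y for _, _, _, y, _, _ in libraries],
            "stage": [s for _, _, _, _, s, _ in libraries],
            "replicate": [rep for *_, rep in libraries],
            "total_mapped": totals,
        }
    )

    # --- metabolite records ----------------------------------------------
    met_rows = []
    for j, (cid, form) in enumerate(zip(compound_ids, compound_forms)):
        for ci, (region, year, stage) in enumerate(cells):
            for rep in range(1, config.metab_reps_per_cell + 1):
                conc = float(
                    2.0
                    ** (
                        c_latent[j, ci]
                        + rng.normal(0.0, config.metab_replicate_noise_sd)
                    )
                )
                met_rows.append(
                    {
                        "compound": cid,
                        "form": form,
                        "region": region,
                        "year": year,
                        "stage": stage,
                        "replicate": rep,
                        "concentration_ug_l": conc,
                    }
                )
    metabolites = pd.DataFrame(met_rows)
    thresholds = pd.DataFrame(
        {
            "compound": compound_ids,
            "threshold_ug_l": np.round(
                2.0 ** rng.normal(np.log2(25.0), 1.0, n_c), 3
            ),
        }
    )

    # --- qPCR table -------------------------------------------------------
    qpcr_targets = [t for t in effect_by_target if t in id_index][:9]
    if not qpcr_targets:
        qpcr_targets = ids[:3]
    ref_genes = ("ref_GAPDH", "ref_actin", "ref_ubiquitin")
    qpcr_rows = []
    for ci, (region, year, stage) in enumerate(cells):
        for biorep in (1, 2):
            sample = f"{region}_{year}_{stage}_b{biorep}"
            ref_cts = {
                ref: rng.normal(20.0, 0.15) for ref in ref_genes
            }
            for ref, ct in ref_cts.items():
                for tech in range(3):
                    qpcr_rows.append(
                        {
                            "sample": sample,
                            "gene": ref,
                            "role": "reference",
                            "technical_rep": tech + 1,
                            "ct": round(ct + rng.normal(0.0, 0.05), 4),
                        }
                    )
            geo = float(np.exp(np.mean(np.log(list(ref_cts.values())))))
            for t in qpcr_targets:
                i = id_index[t]
                e = latent[i, ci] - latent[i].mean()
                ct_t = geo - e + rng.normal(0.0, 0.2)
                for tech in range(3):
                    qpcr_rows.append(
                        {
                            "sample": sample,
                            "gene": t,
                            "role": "target",
                            "technical_rep": tech + 1,
                            "ct": round(ct_t + rng.normal(0.0, 0.05), 4),
                        }
                    )
    qpcr = pd.DataFrame(qpcr_rows)

    # --- climate table (published layout, fresh values) -------------------
    clim_rows = []
    for region in config.regions:
        arid = region == "GT" or region != config.regions[0]
        for year in config.years:
            for phase in climate_mod.PHENOPHASES:
                days = int(rng.integers(5, 15) if phase == "Flowering"
                           else rng.integers(15, 60))
                sun_per_day = rng.normal(9.0 if arid else 6.0, 0.8)
                rain = float(
                    rng.gamma(2.0, 8.0 if arid else 60.0)
                    * (0.0 if phase == "Flowering" and arid else 1.0)
                )
                clim_rows.append(
                    {
                        "region": region,
                        "year": year,
                        "phenophase": phase,
                        "days": days,
                        "rad_kj_m2": round(days * rng.normal(1900.0, 150.0), 0),
                        "gdd": round(days * rng.normal(9.0, 1.5), 2),
                        "sunshine_h": round(max(0.0, days * sun_per_day), 2),
                        "rainfall_mm": round(max(0.0, rain), 2),
                        "temp_diff_c": round(
                            rng.normal(13.5 if arid else 7.5, 1.2), 2
                        ),
                    }
                )
    climate = pd.DataFrame(clim_rows)

    cell_labels = [f"{r}|{y}|{s}" for r, y, s in cells]
    truth_rows = {}
    for fid in sorted(planted_ids):
        if fid in id_index:
            truth_rows[fid] = latent[id_index[fid]]
        else:
            truth_rows[fid] = c_latent[cmpd_index[fid]]
    planted_truth = pd.DataFrame.from_dict(
        truth_rows, orient="index", columns=cell_labels
    )
    planted_truth.index.name = "feature"

    manifest = {
        "config": _config_dict(config),
        "effects": [_effect_dict(e) for e in effects],
        "seed": config.seed,
        "n_libraries": len(lib_ids),
        "n_metabolite_samples": int(
            len(cells) * config.metab_reps_per_cell
        ),
    }
    return Bundle(
        planted_truth=planted_truth,
        transcripts=transcripts,
        library_meta=library_meta,
        unique_counts=unique_counts,
        multiread_groups=multiread_groups,
        metabolites=metabolites,
        thresholds=thresholds,
        qpcr=qpcr,
        climate=climate,
        manifest=manifest,
    )


def _config_dict(config: DesignConfig) -> dict:
    d = dataclasses.asdict(config)
    d["regions"] = list(d["regions"])
    d["years"] = list(d["years"])
    d["stages"] = list(d["stages"])
    return d


def _effect_dict(eff: PlantedEffect) -> dict:
    d = dataclasses.asdict(eff)
    d["partners"] = [dataclasses.asdict(p) for p in eff.partners]
    return d


# ---------------------------------------------------------------------------
# worked fixture: tiny, fully deterministic, hand-checkable
# ---------------------------------------------------------------------------


def make_worked_fixture() -> Bundle:
    """A small fixed bundle whose numbers can be verified by hand.

    Eight genes, four compounds, the full 24-library / 32-sample design.
    Highlights: gene ``HDRlike`` has strictly increasing counts across
    stages (trend class "increased") and a 3-fold CL boost at harvest;
    genes ``A`` and ``B`` share a multi-read group with unique counts 30
    and 10 per library, so a group multiplicity of 100 splits 75/25;
    ``HOUSE1`` is a large constant-count housekeeping filler so that no
    single gene dominates a library; per-library total mapped reads equal
    the sum of unique counts plus multi-read multiplicities by
    construction.
    """
    config = DesignConfig(seed=0)
    genes = [
        ("HDRlike", 1500, "MEP"),
        ("GT14like", 1400, "UGT"),
        ("A", 1000, "TPS-b"),
        ("B", 2000, "TPS-b"),
        ("TFpos", 1200, "TF"),
        ("TFneg", 1100, "TF"),
        ("RIP1", 1000, "ripening"),
        ("HOUSE1", 1000, "other"),
    ]
    transcripts = pd.DataFrame(genes, columns=["transcript", "length_nt", "category"])

    def cell_counts(region: str, s: int) -> dict[str, int]:
        cl = region == "CL"
        return {
            "HDRlike": 100 * (s + 1) * (3 if cl and s == 3 else 1),
            "GT14like": 60 * (s + 1) * (3 if cl and s == 3 else 1),
            "A": 30,
            "B": 10,
            "TFpos": 50 * (s + 1),
            "TFneg": 100 * (4 - s),
            "RIP1": 10 * (s + 1) * (s + 1),
            "HOUSE1": 10000,
        }

    lib_rows, uniq_cols, group_rows = [], {}, []
    for region in config.regions:
        for year in config.years:
            for stage in config.stages:
                s = config.stages.index(stage)
                for rep in range(1, config.libs_per_cell[stage] + 1):
                    lib = f"{region}_{year}_{stage}_rep{rep}"
                    cc = cell_counts(region, s)
                    uniq_cols[lib] = cc
                    group_rows.append(
                        {
                            "library": lib,
                            "group_id": "grp_AB",
                            "candidates": "A;B",
                            "multiplicity": 100,
                        }
                    )
                    lib_rows.append(
                        {
                            "library": lib,
                            "region": region,
                            "year": year,
                            "stage": stage,
                            "replicate": rep,
                            "total_mapped": sum(cc.values()) + 100,
                        }
                    )
    unique_counts = pd.DataFrame(uniq_cols)
    unique_counts.index.name = "transcript"
    library_meta = pd.DataFrame(lib_rows)
    multiread_groups = pd.DataFrame(group_rows)

    compounds = [
        ("free_linalool", "free", 25.2),
        ("free_geraniol", "free", 20.0),
        ("bound_geranyl_glucoside", "bound", 110.0),
        ("bound_neryl_glucoside", "bound", 400.0),
    ]
    met_rows = []
    for cid, form, _thr in compounds:
        for region in config.regions:
            cl = region == "CL"
            for year in config.years:
                for stage in config.stages:
                    s = config.stages.index(stage)
                    base = {"free_linalool": 10.0, "free_geraniol": 8.0,
                            "bound_geranyl_glucoside": 20.0,
                            "bound_neryl_glucoside": 30.0}[cid]
                    conc = base * (s + 1) * (2 if cl and s == 3 else 1)
                    for rep, factor in ((1, 0.9), (2, 1.1)):
                        met_rows.append(
                            {
                                "compound": cid,
                                "form": form,
                                "region": region,
                                "year": year,
                                "stage": stage,
                                "replicate": rep,
                                "concentration_ug_l": conc * factor,
                            }
                        )
    metabolites = pd.DataFrame(met_rows)
    thresholds = pd.DataFrame(
        [(cid, thr) for cid, _form, thr in compounds],
        columns=["compound", "threshold_ug_l"],
    )

    qpcr_rows = []
    for region in config.regions:
        for year in config.years:
            for stage in config.stages:
                s = config.stages.index(stage)
                sample = f"{region}_{year}_{stage}_b1"
                for ref in ("ref_GAPDH", "ref_actin", "ref_ubiquitin"):
                    qpcr_rows.append(
                        {"sample": sample, "gene": ref, "role": "reference",
                         "technical_rep": 1, "ct": 20.0}
                    )
                # 2^-dCT doubles per stage: CT falls by 1 per stage step
                qpcr_rows.append(
                    {"sample": sample, "gene": "HDRlike", "role": "target",
                     "technical_rep": 1, "ct": 25.0 - s}
                )
    qpcr = pd.DataFrame(qpcr_rows)

    manifest = {
        "config": _config_dict(config),
        "effects": [],
        "seed": 0,
        "fixture": "worked",
        "n_libraries": len(library_meta),
        "n_metabolite_samples": 32,
    }
    return Bundle(
        transcripts=transcripts,
        library_meta=library_meta,
        unique_counts=unique_counts,
        multiread_groups=multiread_groups,
        metabolites=metabolites,
        thresholds=thresholds,
        qpcr=qpcr,
        climate=climate_mod.reference_climate(),
        manifest=manifest,
    )
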