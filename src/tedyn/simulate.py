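"""Synthetic genome-pair and cohort simulator with exact ground truth.

Emulates the comparative setting the analysis modules assume: an ancestral
genome splits into two lineages (default 5.88 Mya apart) that accumulate
neutral K2P substitutions at rate r = 1e-8 per site per year; LTR
retrotransposon insertions of known age are planted with identical LTRs at
insertion time, 5-bp target-site duplications and internal coding domains
in Copia or Gypsy order.  Insertions older than the split are shared by
both genomes (and may be partially deleted in one); younger insertions are
lineage-specific.  A cultivar cohort with per-element allele frequencies
yields per-cultivar deletion calls, optionally with spurious noise calls.

Every coordinate, age, lineage assignment and cohort presence flag is
recorded in a truth ledger, and runs are byte-reproducible from the seed.

The mutation process is an exact per-site K2P draw (transition rate alpha,
transversion rate 2*beta, alpha/beta = kappa, total rate r), so the K2P
estimator used for dating is a correctly specified model — dating recovery
on these genomes is a fair test of the estimator, not of model mismatch.
Background indels are off by default, which keeps ancestral coordinates
exactly mappable; a small-indel mode exists for stress tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import DomainHit, LTRElement
from . import io as tio

# base encoding chosen so that xor 1 is a transition (A<->G, C<->T)
_BASES = np.frombuffer(b"AGCT", dtype="S1")
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4}

FATES = ("conserved", "specific_a", "specific_b", "partial_a_in_b", "partial_b_in_a")

DOMAIN_LENGTHS = {"GAG": 400, "PR": 150, "INT": 300, "RT": 450, "RH": 250}
COPIA_ORDER = ("GAG", "PR", "INT", "RT", "RH")
GYPSY_ORDER = ("GAG", "PR", "RT", "RH", "INT")


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 1_200_000  # ancestral backbone, bp
    gc_content: float = 0.375
    n_families: int = 6
    ltr_length: int = 500
    internal_length: int = 2000
    split_time_mya: float = 5.88
    substitution_rate: float = 1e-8
    kappa: float = 2.0
    n_conserved: int = 50
    n_specific_a: int = 50
    n_specific_b: int = 50
    n_partial_a_in_b: int = 25
    n_partial_b_in_a: int = 25
    conserved_age_max_mya: float = 12.0
    specific_age_min_mya: float = 0.1
    specific_age_dist: str = "uniform"  # uniform | burst
    indel_rate: float = 0.0  # expected indel-affected fraction per lineage
    mean_indel_length: float = 3.0
    tsd_length: int = 5
    n_region_count: int = 0
    n_region_length: int = 300
    min_spacing: int = 2000
    edge_margin: int = 1500
    # cohort
    cohort_size: int = 10
    allele_frequency_spectrum: dict = field(
        default_factory=lambda: {1.0: 0.7, 0.9: 0.15, 0.5: 0.15}
    )
    old_polymorphic_fraction: float = 0.0  # pre-split insertions forced polymorphic
    old_polymorphic_frequency: float = 0.5
    deletion_noise_rate: float = 0.0  # spurious calls per element per cultivar
    support_mean: float = 40.0
    noise_support_mean: float = 8.0  # spurious calls are low-support events

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise SimConfigError("gc_content must be in (0,1)")
        if self.substitution_rate <= 0 or self.kappa <= 0:
            raise SimConfigError("rates must be positive")
        counts = self.fate_counts()
        if any(v < 0 for v in counts.values()):
            raise SimConfigError("fate counts must be >= 0")
        m = sum(counts.values())
        need = 2 * self.edge_margin + (m + 1) * self.min_spacing
        if need > self.genome_length:
            raise SimConfigError(
                f"cannot pack {m} insertion sites with spacing {self.min_spacing} "
                f"into a {self.genome_length} bp backbone"
            )
        if self.internal_length < 300:
            raise SimConfigError("internal_length too short for a domain layout")

    def fate_counts(self) -> dict[str, int]:
        return {
            "conserved": self.n_conserved,
            "specific_a": self.n_specific_a,
            "specific_b": self.n_specific_b,
            "partial_a_in_b": self.n_partial_a_in_b,
            "partial_b_in_a": self.n_partial_b_in_a,
        }


@dataclass
class Family:
    family_id: str
    superfamily: str
    ltr: np.ndarray
    internal: np.ndarray
    domain_spans: list[tuple[str, int, int]]  # element coordinates


@dataclass
class SimTruth:
    elements: pd.DataFrame
    n_regions: dict[str, dict[str, list[tuple[int, int]]]]
    mass_check: dict[str, dict[str, int]]
    config: SimConfig


@dataclass
class SimResult:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    elements_a: list[LTRElement]
    elements_b: list[LTRElement]
    domains_a: dict[str, list[DomainHit]]
    domains_b: dict[str, list[DomainHit]]
    truth: SimTruth


@dataclass
class CohortResult:
    genome: str
    calls: dict[str, list]  # cultivar -> [DeletionCall]
    presence: pd.DataFrame  # elements x cultivars, bool
    allele_frequency: dict[str, float]
    noise_calls: list


# ---------------------------------------------------------------------------
# sequence helpers


def random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


def decode(arr: np.ndarray) -> str:
    lookup = np.frombuffer(b"AGCTN", dtype="S1")
    return lookup[arr].tobytes().decode()


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


def k2p_probabilities(t_years: float, rate: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) on one branch of
    length ``t_years`` under K2P with total rate ``rate`` and ts/tv rate
    ratio ``kappa``."""
    beta = rate / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t_years)
    e2 = math.exp(-2.0 * (alpha + beta) * t_years)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def mutate_k2p(
    arr: np.ndarray, t_years: float, rate: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a sequence along one branch under the exact K2P process."""
    if t_years <= 0:
        return arr.copy()
    p_ts, p_tv = k2p_probabilities(t_years, rate, kappa)
    out = arr.copy()
    acgt = arr < 4
    u = rng.random(arr.shape[0])
    ts_target = arr ^ 1
    tv1 = arr ^ 2
    tv2 = arr ^ 3
    out = np.where(u < p_ts, ts_target, out)
    out = np.where((u >= p_ts) & (u < p_ts + p_tv), tv1, out)
    out = np.where((u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv), tv2, out)
    return np.where(acgt, out, arr).astype(np.int8)


def apply_indels(
    arr: np.ndarray, indel_rate: float, mean_len: float, rng: np.random.Generator,
    gc: float,
) -> tuple[np.ndarray, int]:
    """Scatter small insertions/deletions; returns (sequence, net bp change)."""
    if indel_rate <= 0 or len(arr) == 0:
        return arr, 0
    n_events = rng.poisson(indel_rate * len(arr) / mean_len)
    if n_events == 0:
        return arr, 0
    pieces: list[np.ndarray] = []
    cuts = np.sort(rng.integers(0, len(arr), size=n_events))
    prev = 0
    net = 0
    for cut in cuts:
        pieces.append(arr[prev:cut])
        size = int(rng.geometric(1.0 / mean_len))
        if rng.random() < 0.5:
            ins = random_seq(size, gc, rng)
            pieces.append(ins)
            net += size
            prev = cut
        else:
            prev = min(len(arr), cut + size)
            net -= prev - cut
    pieces.append(arr[prev:])
    return np.concatenate(pieces), net


# ---------------------------------------------------------------------------
# genome-pair simulation


def _make_families(cfg: SimConfig, rng: np.random.Generator) -> list[Family]:
    families = []
    total_dom = sum(DOMAIN_LENGTHS.values())
    scale = min(1.0, 0.85 * cfg.internal_length / total_dom)
    for i in range(cfg.n_families):
        superfamily = "Copia" if i % 2 == 0 else "Gypsy"
        order = COPIA_ORDER if superfamily == "Copia" else GYPSY_ORDER
        lengths = {d: int(DOMAIN_LENGTHS[d] * scale) for d in order}
        spacer = (cfg.internal_length - sum(lengths.values())) // (len(order) + 1)
        spans = []
        pos = cfg.ltr_length + spacer  # element coordinates
        for d in order:
            spans.append((d, pos, pos + lengths[d]))
            pos += lengths[d] + spacer
        families.append(
            Family(
                family_id=f"fam_{i:02d}",
                superfamily=superfamily,
                ltr=random_seq(cfg.ltr_length, cfg.gc_content, rng),
                internal=random_seq(cfg.internal_length, cfg.gc_content, rng),
                domain_spans=spans,
            )
        )
    return families


def _draw_age(fate: str, cfg: SimConfig, rng: np.random.Generator) -> float:
    split = cfg.split_time_mya
    if fate in ("conserved", "partial_a_in_b", "partial_b_in_a"):
        return float(rng.uniform(split * 1.02, cfg.conserved_age_max_mya))
    if cfg.specific_age_dist == "burst":
        # recent retrotransposition burst: most insertions very young
        if rng.random() < 0.8:
            return float(rng.uniform(cfg.specific_age_min_mya, min(3.0, split)))
        return float(rng.uniform(min(3.0, split), split))
    return float(rng.uniform(cfg.specific_age_min_mya, split))


def _site_positions(cfg: SimConfig, m: int, rng: np.random.Generator) -> np.ndarray:
    """m sorted backbone positions with guaranteed spacing (stars and bars)."""
    slack = cfg.genome_length - 2 * cfg.edge_margin - (m + 1) * cfg.min_spacing
    offsets = np.sort(rng.integers(0, slack + 1, size=m))
    return cfg.edge_margin + offsets + cfg.min_spacing * (1 + np.arange(m))


def simulate_genome_pair(cfg: SimConfig | None = None) -> SimResult:
    """Generate the diverged genome pair, annotations, domain tables and truth."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    r, kappa = cfg.substitution_rate, cfg.kappa
    split_years = cfg.split_time_mya * 1e6

    backbone = random_seq(cfg.genome_length, cfg.gc_content, rng)

    # assembly-gap regions on the ancestral backbone (shared positions)
    fates: list[str] = []
    for fate, n in cfg.fate_counts().items():
        fates.extend([fate] * n)
    rng.shuffle(fates)
    m = len(fates)
    sites = _site_positions(cfg, m, rng) if m else np.array([], dtype=int)

    if cfg.n_region_count:
        # place N runs midway between insertion sites, clear of every flank
        gaps = []
        bounds = [cfg.edge_margin] + list(sites) + [cfg.genome_length - cfg.edge_margin]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mid = (lo + hi) // 2
            if hi - lo > cfg.n_region_length + 1200:
                gaps.append(mid)
        chosen = rng.choice(len(gaps), size=min(cfg.n_region_count, len(gaps)), replace=False)
        for gi in sorted(chosen):
            s = gaps[gi] - cfg.n_region_length // 2
            backbone[s : s + cfg.n_region_length] = 4

    families = _make_families(cfg, rng)

    # per-element state at the split (shared) or at insertion (specific)
    elements: list[dict] = []
    for idx, fate in enumerate(fates):
        fam = families[int(rng.integers(0, len(families)))]
        age = _draw_age(fate, cfg, rng)
        spec = {
            "element_id": f"elem_{idx:04d}",
            "family_id": fam.family_id,
            "superfamily": fam.superfamily,
            "fate": fate,
            "true_age_mya": age,
            "site": int(sites[idx]),
            "family": fam,
        }
        if fate in ("conserved", "partial_a_in_b", "partial_b_in_a"):
            t1 = (age - cfg.split_time_mya) * 1e6
            spec["shared"] = {
                "ltr5": mutate_k2p(fam.ltr, t1, r, kappa, rng),
                "ltr3": mutate_k2p(fam.ltr, t1, r, kappa, rng),
                "internal": mutate_k2p(fam.internal, t1, r, kappa, rng),
            }
        elements.append(spec)

    backbone_a = mutate_k2p(backbone, split_years, r, kappa, rng)
    backbone_b = mutate_k2p(backbone, split_years, r, kappa, rng)

    result: dict[str, dict] = {}
    for lineage, lineage_backbone in (("A", backbone_a), ("B", backbone_b)):
        result[lineage] = _assemble_lineage(
            lineage, lineage_backbone, sites, elements, cfg, rng
        )

    rows = []
    for spec in elements:
        row = {
            "element_id": spec["element_id"],
            "family_id": spec["family_id"],
            "superfamily": spec["superfamily"],
            "fate": spec["fate"],
            "true_age_mya": spec["true_age_mya"],
        }
        for lineage in ("A", "B"):
            info = result[lineage]["coords"].get(spec["element_id"])
            tag = lineage.lower()
            if info is None:
                row.update({f"present_{tag}": False, f"start_{tag}": -1, f"end_{tag}": -1,
                            f"full_length_{tag}": False})
            else:
                row.update(
                    {
                        f"present_{tag}": True,
                        f"start_{tag}": info["span"][0],
                        f"end_{tag}": info["span"][1],
                        f"full_length_{tag}": info["full_length"],
                    }
                )
        rows.append(row)
    truth_df = pd.DataFrame(rows)

    genome_a = {"chrA": decode(result["A"]["genome"])}
    genome_b = {"chrB": decode(result["B"]["genome"])}
    truth = SimTruth(
        elements=truth_df,
        n_regions={
            "A": {"chrA": tio.find_n_regions(genome_a["chrA"])},
            "B": {"chrB": tio.find_n_regions(genome_b["chrB"])},
        },
        mass_check={
            lineage: {
                "ancestral_bp": cfg.genome_length,
                "inserted_bp": result[lineage]["inserted_bp"],
                "indel_net_bp": result[lineage]["indel_net_bp"],
                "final_bp": len(result[lineage]["genome"]),
            }
            for lineage in ("A", "B")
        },
        config=cfg,
    )
    return SimResult(
        genome_a=genome_a,
        genome_b=genome_b,
        elements_a=result["A"]["annotations"],
        elements_b=result["B"]["annotations"],
        domains_a=result["A"]["domains"],
        domains_b=result["B"]["domains"],
        truth=truth,
    )


def _assemble_lineage(lineage, backbone, sites, elements, cfg, rng):
    r, kappa = cfg.substitution_rate, cfg.kappa
    split_years = cfg.split_time_mya * 1e6
    seq_id = f"chr{lineage}"
    frags = np.split(backbone, sites) if len(sites) else [backbone]
    # background indels in the inter-element backbone only, so element
    # coordinates stay exact
    indel_net = 0
    if cfg.indel_rate > 0:
        new_frags = []
        for frag in frags:
            frag2, net = apply_indels(frag, cfg.indel_rate, cfg.mean_indel_length, rng,
                                      cfg.gc_content)
            indel_net += net
            new_frags.append(frag2)
        frags = new_frags

    parts = [frags[0]]
    pos = len(frags[0])
    coords: dict[str, dict] = {}
    annotations: list[LTRElement] = []
    domains: dict[str, list[DomainHit]] = {}
    inserted_bp = 0
    for i, spec in enumerate(elements):
        fate = spec["fate"]
        present_full = (
            fate == "conserved"
            or (fate == "specific_a" and lineage == "A")
            or (fate == "specific_b" and lineage == "B")
            or (fate == "partial_a_in_b" and lineage == "A")
            or (fate == "partial_b_in_a" and lineage == "B")
        )
        present_remnant = (fate == "partial_a_in_b" and lineage == "B") or (
            fate == "partial_b_in_a" and lineage == "A"
        )
        if present_full or present_remnant:
            fam = spec["family"]
            if "shared" in spec:
                ltr5 = mutate_k2p(spec["shared"]["ltr5"], split_years, r, kappa, rng)
                ltr3 = mutate_k2p(spec["shared"]["ltr3"], split_years, r, kappa, rng)
                internal = mutate_k2p(spec["shared"]["internal"], split_years, r, kappa, rng)
            else:
                t = spec["true_age_mya"] * 1e6
                ltr5 = mutate_k2p(fam.ltr, t, r, kappa, rng)
                ltr3 = mutate_k2p(fam.ltr, t, r, kappa, rng)
                internal = mutate_k2p(fam.internal, t, r, kappa, rng)
            elem = np.concatenate([ltr5, internal, ltr3])
            full_length = True
            if present_remnant:
                # delete 40-70% of the element, starting inside the internal region
                frac = rng.uniform(0.4, 0.7)
                del_len = int(frac * len(elem))
                max_start = len(elem) - del_len - 50
                del_start = int(rng.integers(len(ltr5) // 2, max(len(ltr5) // 2 + 1, min(len(ltr5) + 200, max_start))))
                elem = np.concatenate([elem[:del_start], elem[del_start + del_len :]])
                full_length = False
            tsd = frags[i + 1][: cfg.tsd_length]
            parts.append(tsd)
            pos += len(tsd)
            start = pos
            parts.append(elem)
            pos += len(elem)
            inserted_bp += len(tsd) + len(elem)
            coords[spec["element_id"]] = {"span": (start, pos), "full_length": full_length}
            if full_length:
                ltr_len = len(ltr5)
                el = LTRElement(
                    element_id=spec["element_id"],
                    sequence_id=seq_id,
                    span=(start, pos),
                    ltr5_span=(start, start + ltr_len),
                    ltr3_span=(pos - ltr_len, pos),
                    internal_span=(start + ltr_len, pos - ltr_len),
                    tsd=decode(tsd),
                    superfamily=fam.superfamily,
                    completeness="complete",
                )
                annotations.append(el)
                domains[spec["element_id"]] = [
                    DomainHit(domain=d, span_on_element=(s, e), strand="+")
                    for d, s, e in fam.domain_spans
                ]
        parts.append(frags[i + 1])
        pos += len(frags[i + 1])
    genome = np.concatenate(parts) if parts else np.array([], dtype=np.int8)
    return {
        "genome": genome,
        "coords": coords,
        "annotations": annotations,
        "domains": domains,
        "inserted_bp": inserted_bp,
        "indel_net_bp": indel_net,
    }


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    sim: SimResult,
    cfg: SimConfig | None = None,
    genome: str = "A",
    seed: int | None = None,
) -> CohortResult:
    """Per-cultivar deletion calls and the true presence matrix.

    Each insertion present in the chosen genome receives an allele
    frequency from the configured spectrum (pre-split insertions can be
    forced polymorphic via ``old_polymorphic_fraction``); a cultivar not
    carrying the insertion yields a deletion call spanning it, with
    Poisson-distributed supporting reads.  Spurious calls at random
    positions model caller noise.
    """
    from .polymorphism import DeletionCall

    cfg = cfg or (sim.truth.config if sim.truth else SimConfig())
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    tag = genome.lower()
    seq_id = f"chr{genome}"
    genome_seq = (sim.genome_a if genome == "A" else sim.genome_b)[seq_id]
    elements = sim.truth.elements
    present = elements[elements[f"present_{tag}"] & elements[f"full_length_{tag}"]]
    cultivars = [f"cv_{i:02d}" for i in range(cfg.cohort_size)]

    freqs = sorted(cfg.allele_frequency_spectrum)
    weights = np.array([cfg.allele_frequency_spectrum[f] for f in freqs], dtype=float)
    weights = weights / weights.sum()

    allele_freq: dict[str, float] = {}
    presence = pd.DataFrame(True, index=present["element_id"].tolist(), columns=cultivars)
    calls: dict[str, list] = {c: [] for c in cultivars}
    for row in present.itertuples(index=False):
        eid = row.element_id
        if (
            cfg.old_polymorphic_fraction > 0
            and row.true_age_mya > cfg.split_time_mya
            and rng.random() < cfg.old_polymorphic_fraction
        ):
            f = cfg.old_polymorphic_frequency
        else:
            f = float(freqs[int(rng.choice(len(freqs), p=weights))])
        allele_freq[eid] = f
        span = (int(getattr(row, f"start_{tag}")) - cfg.tsd_length,
                int(getattr(row, f"end_{tag}")))
        for cv in cultivars:
            carried = True if f >= 1.0 else bool(rng.random() < f)
            presence.loc[eid, cv] = carried
            if not carried:
                calls[cv].append(
                    DeletionCall(
                        cultivar_id=cv,
                        sequence_id=seq_id,
                        span=span,
                        support_reads=int(rng.poisson(cfg.support_mean)),
                    )
                )

    noise_calls = []
    if cfg.deletion_noise_rate > 0:
        glen = len(genome_seq)
        for cv in cultivars:
            n_noise = rng.poisson(cfg.deletion_noise_rate * max(1, len(present)))
            for _ in range(n_noise):
                length = int(rng.integers(100, 3000))
                s = int(rng.integers(0, max(1, glen - length)))
                call = DeletionCall(
                    cultivar_id=cv,
                    sequence_id=seq_id,
                    span=(s, s + length),
                    support_reads=int(rng.poisson(cfg.noise_support_mean)),
                )
                calls[cv].append(call)
                noise_calls.append(call)
    return CohortResult(
        genome=genome,
        calls=calls,
        presence=presence,
        allele_frequency=allele_freq,
        noise_calls=noise_calls,
    )


# ---------------------------------------------------------------------------
# presets and output


def peach_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Recent retrotransposition burst; every insertion fixed in the cohort."""
    cfg = SimConfig(
        seed=seed,
        genome_length=500_000,
        n_conserved=15,
        n_specific_a=60,
        n_specific_b=0,
        n_partial_a_in_b=0,
        n_partial_b_in_a=0,
        specific_age_dist="burst",
        allele_frequency_spectrum={1.0: 1.0},
        old_polymorphic_fraction=0.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def almond_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Uniform insertion ages; 30% of pre-split insertions still polymorphic."""
    cfg = SimConfig(
        seed=seed,
        genome_length=500_000,
        n_conserved=40,
        n_specific_a=35,
        n_specific_b=0,
        n_partial_a_in_b=0,
        n_partial_b_in_a=0,
        specific_age_dist="uniform",
        allele_frequency_spectrum={1.0: 1.0},
        old_polymorphic_fraction=0.30,
        old_polymorphic_frequency=0.5,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def write_outputs(sim: SimResult, outdir: str | Path, cohort: CohortResult | None = None) -> dict:
    """Emit FASTA/GFF3/domain-TSV/truth files (and cohort VCFs); returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for tag, genome, elems, doms in (
        ("A", sim.genome_a, sim.elements_a, sim.domains_a),
        ("B", sim.genome_b, sim.elements_b, sim.domains_b),
    ):
        fa = outdir / f"genome_{tag}.fa"
        tio.write_fasta(fa, genome)
        gff = outdir / f"elements_{tag}.gff3"
        tio.write_elements_gff3(gff, elems)
        dom = outdir / f"domains_{tag}.tsv"
        tio.write_domain_tsv(dom, doms)
        manifest[f"genome_{tag}"] = str(fa)
        manifest[f"elements_{tag}"] = str(gff)
        manifest[f"domains_{tag}"] = str(dom)
    truth_tsv = outdir / "truth_elements.tsv"
    sim.truth.elements.to_csv(truth_tsv, sep="\t", index=False)
    manifest["truth_elements"] = str(truth_tsv)
    meta = {
        "n_regions": sim.truth.n_regions,
        "mass_check": sim.truth.mass_check,
        "config": asdict(sim.truth.config),
    }
    truth_json = outdir / "truth_meta.json"
    truth_json.write_text(json.dumps(meta, indent=2, default=str))
    manifest["truth_meta"] = str(truth_json)
    if cohort is not None:
        lengths = {
            name: len(seq)
            for name, seq in (sim.genome_a if cohort.genome == "A" else sim.genome_b).items()
        }
        for cv, cv_calls in cohort.calls.items():
            path = outdir / f"deletions_{cv}.vcf"
            tio.write_deletions_vcf(path, cv_calls, lengths, sample=cv)
            manifest[f"deletions_{cv}"] = str(path)
        presence_tsv = outdir / "truth_presence.tsv"
        cohort.presence.to_csv(presence_tsv, sep="\t")
        manifest["truth_presence"] = str(presence_tsv)
    return manifest
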