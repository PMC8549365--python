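"""Synthetic data emulating the study design end to end.

Three generators close the loop for every pipeline stage:

* :func:`simulate_oisl_tree` — evolves CRISPR arrays down a random
  coalescent genealogy (from msprime) under ordered independent spacer
  loss: each spacer is lost at rate 1 per lineage, new spacers are
  inserted at the leader end at relative rate ``rho``. With ``rho = 0``
  every tip is a pure-deletion derivative of the ancestral array — the
  nested-deletion architecture observed in natural arrays dominated by
  spacer loss.
* :func:`simulate_hierarchy` — draws read-level records for a nested
  region > habitat > site > host design, with per-level differentiation
  weights mixing fresh Dirichlet profiles into the parent profile. Strong
  region-level and weak habitat-level weights reproduce the
  strong-region/weak-habitat variance pattern of the study system.
* :func:`simulate_reads` — renders each record as a CCS-like amplicon:
  ``primerF + repeat + (spacer + repeat)* + primerR`` with i.i.d.
  substitution/indel errors, random strand, and configurable broken-read
  fractions (primer dropout, truncation) to exercise every QC category.

All randomness flows from ``SimConfig.seed``; the same config is
byte-for-byte reproducible.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import CrisprArray, Spacer, SpacerCatalog
from .errors import ExtinctArray
from .matching import revcomp
from .phylo import RootedTree, TreeNode
from .popstruct import SampleHierarchy

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-shaped defaults; every knob is overridable.

    The default design mirrors the sampled system: 3 regions with 2
    habitats each, 2 sites per habitat and 3 hosts per site; ~123
    haplotypes descending from one long ancestral array by spacer deletion
    only (``rho = 0``); 200 CCS-like reads per sample with 0.5 %
    substitution + 0.5 % indel error. Differentiation weights put strong
    structure at the region level, weak structure at the habitat level and
    moderate host-to-host variation.
    """

    seed: int = 0
    # --- array evolution ---
    ancestor_length: int = 60
    rho: float = 0.0
    n_haplotypes: int = 123
    time_scale: float = 0.15  # deletions per spacer per coalescent time unit
    spacer_length: int = 35
    repeat_length: int = 30
    primer_length: int = 24
    max_retries: int = 10
    # --- hierarchy ---
    n_regions: int = 3
    n_habitats: int = 2
    n_sites: int = 2
    n_hosts: int = 3
    n_sections: int = 1
    n_replicates: int = 1
    depth: int = 200
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "region": 0.9,
            "habitat": 0.05,
            "site": 0.05,
            "host": 0.3,
        }
    )
    dirichlet_alpha: float = 0.3
    disjoint_regions: bool = False
    # --- read rendering ---
    sub_rate: float = 0.005
    indel_rate: float = 0.005
    primer_dropout: float = 0.0
    truncate_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("rho", "sub_rate", "indel_rate", "primer_dropout",
                     "truncate_frac", "time_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def random_primers(rng: np.random.Generator, length: int = 24) -> tuple[str, str]:
    """A forward/reverse primer pair (reverse given 5'->3' on the - strand)."""
    return _random_dna(rng, length), _random_dna(rng, length)


# ---------------------------------------------------------------------------
# Array evolution
# ---------------------------------------------------------------------------

def _coalescent_tree(n: int, time_scale: float, seed: int) -> RootedTree:
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1, random_seed=max(1, seed)
    )
    t = ts.first()
    times = {u: t.time(u) for u in t.nodes()}

    def build(u: int) -> TreeNode:
        kids = list(t.children(u))
        if not kids:
            return TreeNode(name=f"T{u + 1}")
        node = TreeNode(children=[build(c) for c in kids])
        for child_node, c in zip(node.children, kids):
            child_node.length = (times[u] - times[c]) * time_scale
        return node

    return RootedTree(root=build(t.root))


def _evolve(
    tree: RootedTree,
    ancestor: list[int],
    rho: float,
    rng: np.random.Generator,
    next_id: list[int],
) -> dict[str, list[int]]:
    tips: dict[str, list[int]] = {}

    def walk(node: TreeNode, state: list[int]) -> None:
        if node.is_leaf:
            tips[node.name] = state
            return
        for child in node.children:
            b = child.length
            keep = rng.random(len(state)) < np.exp(-b)
            surv = [s for s, k in zip(state, keep) if k]
            n_new = rng.poisson(rho * -np.expm1(-b)) if rho > 0 else 0
            new_ids = []
            for _ in range(n_new):
                new_ids.append(next_id[0])
                next_id[0] += 1
            walk(child, new_ids + surv)

    walk(tree.root, list(ancestor))
    return tips


def simulate_oisl_tree(
    config: SimConfig,
) -> tuple[RootedTree, dict[str, CrisprArray], SpacerCatalog]:
    """Evolve arrays along a random genealogy under the spacer-loss model.

    Returns the true tree (branch lengths in expected deletions per
    spacer), the per-tip arrays, and a spacer catalog covering every
    spacer that survives anywhere (fresh sequences, ancestral order as the
    catalog reference when ``rho = 0``).

    Raises
    ------
    ExtinctArray
        If some tip loses every spacer in each of ``max_retries`` attempts.
    """
    rng = np.random.default_rng([config.seed, 1])
    tree = _coalescent_tree(
        config.n_haplotypes,
        config.time_scale,
        int(rng.integers(1, 2**31 - 1)),
    )
    ancestor = list(range(1, config.ancestor_length + 1))
    tips = None
    for _ in range(config.max_retries):
        next_id = [config.ancestor_length + 1]
        cand = _evolve(tree, ancestor, config.rho, rng, next_id)
        if all(cand.values()):
            tips = cand
            break
    if tips is None:
        raise ExtinctArray(
            f"a tip lost all spacers in {config.max_retries} attempts; "
            "lower time_scale or lengthen the ancestor"
        )
    arrays = {name: CrisprArray(ids) for name, ids in sorted(tips.items())}
    used = sorted({i for ids in tips.values() for i in ids} | set(ancestor))
    spacers = [Spacer(id=i, sequence=_random_dna(rng, config.spacer_length))
               for i in used]
    catalog = SpacerCatalog(
        spacers,
        _random_dna(rng, config.repeat_length),
        reference_order=ancestor if config.rho == 0 else None,
    )
    return tree, arrays, catalog


def unique_haplotypes(arrays: Mapping[str, CrisprArray]) -> dict[str, CrisprArray]:
    """Collapse identical tip arrays; keys H1..Hn in stable order."""
    seen: dict[tuple[int, ...], str] = {}
    out: dict[str, CrisprArray] = {}
    for name in sorted(arrays):
        key = arrays[name].spacer_ids
        if key not in seen:
            label = f"H{len(seen) + 1}"
            seen[key] = label
            out[label] = arrays[name]
    return out


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def simulate_hierarchy(
    haplotypes: Mapping[str, CrisprArray] | Sequence[str],
    config: SimConfig,
    region_pools: Sequence[Sequence[str]] | None = None,
) -> SampleHierarchy:
    """Read-level records for a nested region/habitat/site/host design.

    Haplotype frequency profiles are built top-down: each stratum mixes a
    fresh Dirichlet draw into its parent profile with the stratum's
    differentiation weight (weight 0 = identical to parent, weight 1 =
    independent). ``region_pools`` (or ``config.disjoint_regions``)
    restricts each region to its own haplotype subset, giving maximal
    regional differentiation. Every read is one row; one sample = one
    host x section x replicate.
    """
    labels = list(haplotypes) if not isinstance(haplotypes, Mapping) else list(
        haplotypes.keys()
    )
    if len(labels) < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng([config.seed, 2])
    K = len(labels)
    alpha = config.dirichlet_alpha
    w = {lv: float(config.weights.get(lv, 0.0)) for lv in
         ("region", "habitat", "site", "host")}

    if region_pools is None and config.disjoint_regions:
        perm = rng.permutation(K)
        region_pools = [
            [labels[i] for i in part]
            for part in np.array_split(perm, config.n_regions)
        ]

    base = rng.dirichlet(np.full(K, alpha))

    def mix(parent: np.ndarray, weight: float, support: np.ndarray) -> np.ndarray:
        fresh = np.zeros(K)
        fresh[support] = rng.dirichlet(np.full(len(support), alpha))
        prof = (1.0 - weight) * parent + weight * fresh
        prof = prof * (np.isin(np.arange(K), support))
        total = prof.sum()
        if total == 0:  # parent had no mass on the support
            prof[support] = 1.0 / len(support)
            total = 1.0
        return prof / total

    rows: list[dict[str, str]] = []
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    for r in range(config.n_regions):
        region = f"R{r + 1}"
        if region_pools is not None:
            support = np.array(sorted(lab_idx[x] for x in region_pools[r]))
        else:
            support = np.arange(K)
        p_region = mix(base, w["region"], support)
        for hb in range(config.n_habitats):
            habitat = f"{region}-Hb{hb + 1}"
            p_hab = mix(p_region, w["habitat"], support)
            for s in range(config.n_sites):
                site = f"{habitat}-S{s + 1}"
                p_site = mix(p_hab, w["site"], support)
                for ho in range(config.n_hosts):
                    host = f"{site}-W{ho + 1}"
                    p_host = mix(p_site, w["host"], support)
                    for sec in range(config.n_sections):
                        section = f"{host}-T{sec + 1}"
                        for rep in range(config.n_replicates):
                            replicate = f"{section}-D{rep + 1}"
                            draws = rng.multinomial(config.depth, p_host)
                            for k in np.flatnonzero(draws):
                                rows.extend(
                                    [{
                                        "region": region,
                                        "habitat": habitat,
                                        "site": site,
                                        "host": host,
                                        "section": section,
                                        "replicate": replicate,
                                        "haplotype_id": labels[k],
                                    }] * int(draws[k])
                                )
    return SampleHierarchy(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, sub: float, indel: float) -> str:
    if sub == 0 and indel == 0:
        return seq
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < indel / 2:
            continue  # deletion
        if r < indel:
            out.append(ch)
            out.append(str(rng.choice(_BASES)))
            continue
        if r < indel + sub:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[int(rng.integers(3))])
            continue
        out.append(ch)
    return "".join(out)


def render_amplicon(
    array: CrisprArray, catalog: SpacerCatalog, primers: tuple[str, str]
) -> str:
    """Error-free amplicon: primerF + repeat + (spacer + repeat)* + primerR."""
    rep = catalog.repeat_sequence
    body = rep + "".join(catalog[i].sequence + rep for i in array)
    return primers[0] + body + revcomp(primers[1])


def simulate_reads(
    h: SampleHierarchy,
    haplotypes: Mapping[str, CrisprArray],
    catalog: SpacerCatalog,
    primers: tuple[str, str],
    config: SimConfig,
) -> dict[str, list[SeqRecord]]:
    """Render every hierarchy row as one CCS-like read, grouped by sample.

    The sample key is the innermost stratum (replicate). Broken reads are
    produced at the configured fractions: ``primer_dropout`` removes one
    primer (and some flank), ``truncate_frac`` truncates the read below
    the minimum usable length. Half the reads are reverse-complemented.
    Quality strings are constant Q40.
    """
    rng = np.random.default_rng([config.seed, 3])
    sample_col = h.levels[-1]
    out: dict[str, list[SeqRecord]] = {}
    for sample, group in h.df.groupby(sample_col, sort=True):
        recs: list[SeqRecord] = []
        for i, hap in enumerate(group["haplotype_id"]):
            seq = render_amplicon(haplotypes[hap], catalog, primers)
            r = rng.random()
            if r < config.primer_dropout:
                cut = len(primers[0]) + int(rng.integers(0, len(catalog.repeat_sequence)))
                seq = seq[cut:] if rng.random() < 0.5 else seq[: len(seq) - cut]
            elif r < config.primer_dropout + config.truncate_frac:
                # keep both primers but shrink the insert below the usable minimum
                keep = int(rng.integers(0, 28))
                seq = (
                    primers[0]
                    + seq[len(primers[0]) : len(primers[0]) + keep]
                    + revcomp(primers[1])
                )
            seq = _mutate(seq, rng, config.sub_rate, config.indel_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rec = SeqRecord(Seq(seq), id=f"{sample}/{i}/{hap}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            recs.append(rec)
        out[str(sample)] = recs
    return out


def write_fastq(reads: Mapping[str, list[SeqRecord]], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in sorted(reads):
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            SeqIO.write(reads[sample], fh, "fastq")
        paths.append(path)
    return paths


def write_primers_fasta(primers: tuple[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">FWD\n{primers[0]}\n>REV\n{primers[1]}\n")


def read_primers_fasta(path: str | Path) -> tuple[str, str]:
    recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    return recs["FWD"], recs["REV"]
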