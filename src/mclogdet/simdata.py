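"""Synthetic pedigrees, SNP genotypes and phenotypes for animal-model inference.

The generator emulates the structure of livestock evaluation data: a
multi-generation pedigree from random mating, SNP genotypes obtained by gene
dropping founder haplotypes down the pedigree, and phenotypes simulated under
a single-trait animal model with contemporary-group fixed effects, an optional
permanent-environment effect, and breeding values built sequentially from
Mendelian sampling deviations (never via a dense factorization of A, so the
simulation scales linearly in pedigree size and is exact by construction).

File dialects (the package's canonical formats, all plain text):

* pedigree CSV: header ``animal,sire,dam``; dense 1-based ids, 0 = unknown.
* genotype file: one line per genotyped animal, ``id`` then a contiguous
  string of per-SNP allele counts, whitespace separated (``17 0120...``).
* phenotype CSV: header ``animal,cg,value`` (one row per record).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .operators import GenotypeSet, ModelFrame, Pedigree, RandomEffect

__all__ = [
    "SimSpec",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_pedigree",
    "read_pedigree",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset.

    ``true_varcomps`` maps effect names to variances in trait units squared
    and must contain ``"animal"`` and ``"residual"``; adding ``"pe"`` turns on
    a permanent-environment effect with ``n_records_per_animal`` repeated
    records.  ``founder_allele_freq`` may be a scalar, a per-SNP array, or
    None to draw frequencies from U(0.1, 0.9).
    """

    n_founders: int = 100
    n_generations: int = 5
    n_offspring: int = 100  # per generation
    n_sires: int = 25  # breeding males drawn from the previous generation
    n_snp: int = 1000
    founder_allele_freq: float | np.ndarray | None = None
    prop_genotyped: float = 0.1
    true_varcomps: dict = field(
        default_factory=lambda: {"animal": 0.3, "residual": 0.7}
    )
    n_cg: int = 20
    n_records_per_animal: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need at least 2 founders and 1 generation")
        if self.n_offspring < 1 or self.n_sires < 1:
            raise ValueError("n_offspring and n_sires must be positive")
        if not 0.0 <= self.prop_genotyped <= 1.0:
            raise ValueError("prop_genotyped must lie in [0, 1]")
        for name, v in self.true_varcomps.items():
            if v <= 0:
                raise ValueError(f"variance {name} must be > 0")
        for key in ("animal", "residual"):
            if key not in self.true_varcomps:
                raise ValueError(f"true_varcomps must include {key!r}")
        h2 = self.h2
        if not 0.0 < h2 < 1.0:
            raise ValueError(f"implied heritability {h2:.3f} outside (0, 1)")

    @property
    def h2(self) -> float:
        total = sum(self.true_varcomps.values())
        return self.true_varcomps["animal"] / total

    @property
    def n_animals(self) -> int:
        return self.n_founders + self.n_generations * self.n_offspring


def _rng(spec: SimSpec, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([spec.seed, tag]))


def simulate_pedigree(spec: SimSpec) -> Pedigree:
    """Multi-generation pedigree by random union of sires and dams.

    Founders (generation 0) have unknown parents.  Each later generation
    draws ``n_offspring`` animals whose sires come from ``n_sires`` randomly
    chosen males and whose dams come from the remaining females of the
    previous generation; sire and dam are always distinct animals.
    """
    rng = _rng(spec, "pedigree")
    n = spec.n_animals
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    gen = np.zeros(n, dtype=np.int64)
    prev = np.arange(1, spec.n_founders + 1)
    pos = spec.n_founders
    for g in range(1, spec.n_generations + 1):
        if prev.size < 2:
            raise ValueError("degenerate spec: fewer than 2 candidate parents")
        n_sires = min(spec.n_sires, prev.size - 1)
        males = rng.choice(prev, size=n_sires, replace=False)
        females = np.setdiff1d(prev, males)
        ids = np.arange(pos + 1, pos + spec.n_offspring + 1)
        sire[ids - 1] = rng.choice(males, size=spec.n_offspring, replace=True)
        dam[ids - 1] = rng.choice(females, size=spec.n_offspring, replace=True)
        gen[ids - 1] = g
        prev = ids
        pos += spec.n_offspring
    return Pedigree(sire=sire, dam=dam, generation=gen)


def _founder_freqs(spec: SimSpec) -> np.ndarray:
    if spec.founder_allele_freq is None:
        return _rng(spec, "freqs").uniform(0.1, 0.9, size=spec.n_snp)
    p = np.broadcast_to(np.asarray(spec.founder_allele_freq, dtype=float), (spec.n_snp,))
    if not np.all((p >= 0.0) & (p <= 1.0)):
        raise ValueError("founder allele frequencies outside [0, 1]")
    return p.copy()


def simulate_genotypes(ped: Pedigree, spec: SimSpec) -> GenotypeSet:
    """SNP genotypes by gene dropping.

    Founders carry two haplotypes drawn from Hardy-Weinberg at the founder
    allele frequencies; every descendant receives one gamete per parent, each
    locus segregating with a fair coin.  The genotyped subset is sampled from
    the youngest generations (mimicking routine genotyping of recent
    animals), sized by ``prop_genotyped``.
    """
    rng = _rng(spec, "genedrop")
    p = _founder_freqs(spec)
    n, m = ped.n, spec.n_snp
    hap = np.zeros((n, 2, m), dtype=np.uint8)
    founders = np.flatnonzero(ped.is_founder)
    hap[founders] = rng.random((founders.size, 2, m)) < p
    non = np.flatnonzero(~ped.is_founder)
    # per-generation vectorized drop (parents always precede offspring)
    gens = ped.generation
    if gens is None:  # derive topological depth so parents are filled first
        gens = np.zeros(n, dtype=np.int64)
        for i in non:
            ps = gens[ped.sire[i] - 1] if ped.sire[i] else 0
            pd_ = gens[ped.dam[i] - 1] if ped.dam[i] else 0
            gens[i] = max(ps, pd_) + 1
    order = [non[gens[non] == g] for g in np.unique(gens[non])]
    cols = np.arange(m)
    for block in order:
        if block.size == 0:
            continue
        s = ped.sire[block] - 1
        d = ped.dam[block] - 1
        pick_s = rng.integers(0, 2, size=(block.size, m))
        pick_d = rng.integers(0, 2, size=(block.size, m))
        hap[block, 0] = hap[s[:, None], pick_s, cols]
        hap[block, 1] = hap[d[:, None], pick_d, cols]
    genotypes = hap.sum(axis=1)

    n_geno = int(round(spec.prop_genotyped * n))
    if n_geno == 0:
        ids = np.empty(0, dtype=np.int64)
    else:
        # youngest animals first, then sample uniformly among them
        pool = np.arange(n - min(n, max(n_geno * 2, spec.n_offspring)), n)
        chosen = np.sort(rng.choice(pool, size=min(n_geno, pool.size), replace=False))
        ids = chosen + 1
    return GenotypeSet(ids=ids, matrix=genotypes[ids - 1] if ids.size else
                       genotypes[:0], freqs=None)


def simulate_phenotypes(
    ped: Pedigree, spec: SimSpec, geno: GenotypeSet | None = None
) -> ModelFrame:
    """Phenotypes under the animal model y = Xb + W u (+ W p) + e.

    Breeding values descend the pedigree by Mendelian sampling,
    u_i = (u_s + u_d)/2 + m_i with m_i ~ N(0, d_i sigma2_u); contemporary
    groups are assigned at random with N(0, 1)-scaled fixed effects; records
    attach to every non-founder (founders stay unphenotyped, as is typical
    when early generations predate recording).
    """
    rng = _rng(spec, "phenotypes")
    vc = spec.true_varcomps
    sigma_u = vc["animal"]
    sigma_e = vc["residual"]
    d = ped.mendelian_variances(with_inbreeding=True)
    n = ped.n
    u = np.zeros(n)
    mend = rng.standard_normal(n) * np.sqrt(d * sigma_u)
    s, m = ped.sire - 1, ped.dam - 1
    for i in range(n):
        parental = 0.0
        if s[i] >= 0:
            parental += 0.5 * u[s[i]]
        if m[i] >= 0:
            parental += 0.5 * u[m[i]]
        u[i] = parental + mend[i]

    recorded = np.flatnonzero(~ped.is_founder) + 1
    if recorded.size == 0:
        recorded = np.arange(1, n + 1)
    reps = max(1, spec.n_records_per_animal if "pe" in vc else 1)
    record_animal = np.repeat(recorded, reps)
    n_rec = record_animal.size

    cg = rng.integers(0, spec.n_cg, size=n_rec)
    # drop empty contemporary groups so X keeps full column rank
    used, cg = np.unique(cg, return_inverse=True)
    cg_effects = rng.standard_normal(used.size)

    y = cg_effects[cg] + u[record_animal - 1]
    rows = np.arange(n_rec)
    X = sp.csr_matrix((np.ones(n_rec), (rows, cg)), shape=(n_rec, used.size))
    W_animal = sp.csr_matrix(
        (np.ones(n_rec), (rows, record_animal - 1)), shape=(n_rec, n)
    )
    kind = "single-step" if (geno is not None and geno.n_geno > 0) else "pedigree"
    effects = [RandomEffect("animal", W_animal, kind=kind)]

    if "pe" in vc:
        pe_levels, pe_idx = np.unique(record_animal, return_inverse=True)
        pe_vals = rng.standard_normal(pe_levels.size) * np.sqrt(vc["pe"])
        y = y + pe_vals[pe_idx]
        W_pe = sp.csr_matrix(
            (np.ones(n_rec), (rows, pe_idx)), shape=(n_rec, pe_levels.size)
        )
        effects.append(RandomEffect("pe", W_pe, kind="identity"))

    y = y + rng.standard_normal(n_rec) * np.sqrt(sigma_e)
    return ModelFrame(
        y=y, X=X, effects=effects, record_animal=record_animal, ped=ped, geno=geno,
        truth={"u": u, "cg_effects": cg_effects, "spec": spec},
    )


def simulate_dataset(spec: SimSpec) -> ModelFrame:
    """Pedigree + genotypes + phenotypes in one call (the usual entry point)."""
    ped = simulate_pedigree(spec)
    geno = simulate_genotypes(ped, spec) if spec.prop_genotyped > 0 else None
    if geno is not None and geno.n_geno == 0:
        geno = None
    return simulate_phenotypes(ped, spec, geno=geno)


# ---------------------------------------------------------------------------
# canonical file dialects
# ---------------------------------------------------------------------------


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    df = pd.DataFrame(
        {"animal": np.arange(1, ped.n + 1), "sire": ped.sire, "dam": ped.dam}
    )
    df.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path)
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree file missing column {col!r}")
    order = np.argsort(df["animal"].to_numpy())
    df = df.iloc[order]
    ids = df["animal"].to_numpy(dtype=np.int64)
    if not np.array_equal(ids, np.arange(1, ids.size + 1)):
        raise ValueError("pedigree ids must be dense 1..n")
    return Pedigree(sire=df["sire"].to_numpy(np.int64), dam=df["dam"].to_numpy(np.int64))


def write_genotypes(geno: GenotypeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, animal in enumerate(geno.ids):
            fh.write(f"{animal} {''.join(map(str, geno.matrix[i]))}\n")


def read_genotypes(path: str | Path) -> GenotypeSet:
    ids: list[int] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id genotypes'")
            ids.append(int(parts[0]))
            rows.append(np.frombuffer(parts[1].encode(), dtype=np.uint8) - ord("0"))
    matrix = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)
    return GenotypeSet(ids=np.asarray(ids, dtype=np.int64), matrix=matrix)


def write_phenotypes(frame: ModelFrame, path: str | Path) -> None:
    cg = np.asarray(frame.X.argmax(axis=1)).ravel() + 1
    pd.DataFrame(
        {"animal": frame.record_animal, "cg": cg, "value": frame.y}
    ).to_csv(path, index=False)


def read_phenotypes(
    path: str | Path,
    ped: Pedigree,
    geno: GenotypeSet | None = None,
    pe: bool = False,
) -> ModelFrame:
    """Rebuild a ModelFrame from the phenotype CSV plus pedigree/genotypes."""
    df = pd.read_csv(path)
    for col in ("animal", "cg", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype file missing column {col!r}")
    animal = df["animal"].to_numpy(np.int64)
    levels, cg = np.unique(df["cg"].to_numpy(), return_inverse=True)
    n_rec = animal.size
    rows = np.arange(n_rec)
    X = sp.csr_matrix((np.ones(n_rec), (rows, cg)), shape=(n_rec, levels.size))
    W = sp.csr_matrix((np.ones(n_rec), (rows, animal - 1)), shape=(n_rec, ped.n))
    kind = "single-step" if (geno is not None and geno.n_geno > 0) else "pedigree"
    effects = [RandomEffect("animal", W, kind=kind)]
    if pe:
        pe_levels, pe_idx = np.unique(animal, return_inverse=True)
        W_pe = sp.csr_matrix(
            (np.ones(n_rec), (rows, pe_idx)), shape=(n_rec, pe_levels.size)
        )
        effects.append(RandomEffect("pe", W_pe, kind="identity"))
    return ModelFrame(
        y=df["value"].to_numpy(float), X=X, effects=effects,
        record_animal=animal, ped=ped, geno=geno,
    )
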