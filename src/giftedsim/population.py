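"""Population experiments: many genomes, many families, many learners.

Each simulated child is a (genome, family environment, network) triple:
the genome decodes to the 16 neurocomputational parameters, the family
quotient fixes the training subset, and the network is trained for the
configured number of epochs with end-of-epoch pruning.  Behavioural
profiles are recorded on a checkpoint grid that is dense early in
development, where the gifted-classification time points fall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .artificial_language import Corpus, CorpusConfig, generate_corpus
from .environment import build_family_set, sample_quotient, ses_split
from .genome import (DEFAULT_SPANS, GeneLayout, LookupTables, build_default_tables,
                     decode, default_layout, sample_genome)
from .network import (DivergenceError, apply_pruning, binary_csr, evaluate,
                      init_network, seed_noise, train_epoch)

logger = logging.getLogger(__name__)

MEASURES = ("regular_pct", "no_change_pct", "vowel_change_pct",
            "arbitrary_pct", "novel_regularized_pct")

PARAM_NAMES = tuple(name for name, _ in DEFAULT_SPANS)


def default_checkpoints(epochs: int, dense_until: int = 150,
                        sparse: tuple = (250, 500, 1000)) -> tuple:
    """Every epoch through the dense early window, then the sparse grid."""
    grid = list(range(1, min(dense_until, epochs) + 1))
    grid += [e for e in sparse if dense_until < e <= epochs]
    return tuple(grid)


@dataclass
class PopulationConfig:
    n_children: int = 1000
    epochs: int = 1000
    checkpoints: tuple | None = None        # None -> default grid
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    evaluate_with_noise: bool = False   # noise shapes learning, not the test
    dtype: str = "float32"          # weight-store precision for population runs

    def resolved_checkpoints(self) -> tuple:
        if self.checkpoints is not None:
            return tuple(sorted(set(self.checkpoints)))
        return default_checkpoints(self.epochs)


@dataclass
class PopulationResults:
    trajectory: pd.DataFrame     # child_id, epoch, five profile measures
    provenance: pd.DataFrame     # child_id, quotient, ses, parameters, genome, seed
    checkpoints: tuple
    master_seed: int
    config: PopulationConfig

    @property
    def n_children(self) -> int:
        return int(self.provenance.shape[0])

    def profile_at(self, epoch: int, measure: str = "regular_pct") -> pd.Series:
        """measure per child at one checkpoint, indexed by child_id."""
        if epoch not in self.checkpoints:
            raise KeyError(f"epoch {epoch} not in checkpoint grid")
        sub = self.trajectory[self.trajectory["epoch"] == epoch]
        return sub.set_index("child_id")[measure].sort_index()

    def measure_wide(self, measure: str = "regular_pct") -> pd.DataFrame:
        """children x checkpoint-epochs matrix of one measure."""
        return self.trajectory.pivot(index="child_id", columns="epoch", values=measure)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(outdir / "trajectory.csv", index=False, float_format="%.10g")
        self.provenance.to_csv(outdir / "provenance.csv", index=False, float_format="%.10g")

    @classmethod
    def load(cls, outdir, master_seed: int = -1,
             config: PopulationConfig | None = None) -> "PopulationResults":
        outdir = Path(outdir)
        traj = pd.read_csv(outdir / "trajectory.csv")
        prov = pd.read_csv(outdir / "provenance.csv", dtype={"genome": str})
        return cls(trajectory=traj, provenance=prov,
                   checkpoints=tuple(sorted(traj["epoch"].unique())),
                   master_seed=master_seed, config=config or PopulationConfig())


def simulate_child(child_id: int, master_seed: int, corpus_patterns: dict,
                   epochs: int, checkpoints: tuple, layout: GeneLayout,
                   tables: LookupTables, evaluate_with_noise: bool = False,
                   dtype=np.float32):
    """Run one child end to end; returns (trajectory rows, provenance dict).

    The child's random streams are split from (master_seed, child_id), so
    results do not depend on population ordering.  A divergent child is
    flagged and its remaining checkpoints are NaN.
    """
    ss = np.random.SeedSequence([master_seed, child_id])
    rng_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(rng_ss)

    genome = sample_genome(rng, layout)
    params = decode(genome, layout, tables)
    quotient = sample_quotient(rng)
    n_verbs = corpus_patterns["X_train"].shape[0]
    mask = build_family_set(n_verbs, quotient, rng)
    if not mask.any():
        mask[int(rng.integers(n_verbs))] = True   # degenerate family: keep one verb

    noise_seed = int(noise_ss.generate_state(1)[0] % np.uint32(2**31))
    seed_noise(noise_seed)
    state = init_network(params, rng, dtype=dtype)

    X_fam = np.ascontiguousarray(corpus_patterns["X_train"][mask], dtype=dtype)
    T_fam = np.ascontiguousarray(corpus_patterns["T_train"][mask], dtype=dtype)
    csr = binary_csr(X_fam)

    cpset = set(checkpoints)
    rows = []
    diverged = False
    for epoch in range(1, epochs + 1):
        try:
            train_epoch(state, X_fam, T_fam, csr=csr)
        except DivergenceError as err:
            logger.warning("child %d diverged at epoch %d: %s", child_id, epoch, err)
            diverged = True
        if not diverged:
            apply_pruning(state)
        if epoch in cpset:
            if diverged:
                rows.append((child_id, epoch) + (np.nan,) * len(MEASURES))
            else:
                profile = evaluate(state, corpus_patterns, with_noise=evaluate_with_noise)
                rows.append((child_id, epoch) + profile.as_tuple())
        if diverged and epoch >= max(cpset):
            break
    if diverged:
        recorded = {r[1] for r in rows}
        for epoch in sorted(cpset - recorded):
            rows.append((child_id, epoch) + (np.nan,) * len(MEASURES))
        rows.sort(key=lambda r: r[1])

    prov = {"child_id": child_id, "quotient": quotient,
            "n_family_verbs": int(mask.sum()),
            "family_mask": "".join("1" if b else "0" for b in mask),
            "seed": noise_seed,
            "diverged": diverged, "genome": genome.to_string()}
    prov.update(params.as_dict())
    return rows, prov


def run_population(n: int = 1000, epochs: int = 1000, checkpoints: tuple | None = None,
                   master_seed: int = 0, config: PopulationConfig | None = None,
                   corpus: Corpus | None = None, progress: bool = False) -> PopulationResults:
    """Simulate a population of n children for the given number of epochs.

    The corpus is generated once from the master seed and shared by all
    children (only the family inclusion masks differ).  Identical master
    seeds give byte-identical trajectory and provenance tables.
    """
    if n < 1:
        raise ValueError("need at least one child")
    config = config or PopulationConfig(n_children=n, epochs=epochs, checkpoints=checkpoints)
    config.n_children, config.epochs = n, epochs
    if checkpoints is not None:
        config.checkpoints = tuple(checkpoints)
    cps = config.resolved_checkpoints()
    if any(e < 1 or e > epochs for e in cps):
        raise ValueError("checkpoints must lie in 1..epochs")

    corpus = corpus or generate_corpus(master_seed, config.corpus)
    dtype = np.dtype(config.dtype)
    patterns = corpus.pattern_arrays()
    from .network import prepare_patterns
    patterns.update(prepare_patterns(patterns, dtype=dtype))

    layout = default_layout()
    tables = build_default_tables(layout)

    all_rows, prov_rows = [], []
    for child_id in range(n):
        rows, prov = simulate_child(child_id, master_seed, patterns, epochs, cps,
                                    layout, tables, config.evaluate_with_noise,
                                    dtype=dtype)
        all_rows.extend(rows)
        prov_rows.append(prov)
        if progress and (child_id + 1) % 10 == 0:
            logger.info("simulated %d/%d children", child_id + 1, n)

    trajectory = pd.DataFrame(all_rows, columns=("child_id", "epoch") + MEASURES)
    provenance = pd.DataFrame(prov_rows)
    ses = ses_split(provenance["quotient"].to_numpy())
    provenance["ses_group"] = ses["ses_group"].to_numpy()
    provenance["ses_quartile"] = ses["ses_quartile"].to_numpy()
    front = ["child_id", "quotient", "ses_group", "ses_quartile", "n_family_verbs"]
    provenance = provenance[front + [c for c in provenance.columns if c not in front]]
    return PopulationResults(trajectory=trajectory, provenance=provenance,
                             checkpoints=cps, master_seed=master_seed, config=config)


def rank_networks(results: PopulationResults, epoch: int,
                  measure: str = "regular_pct") -> pd.Series:
    """Population ranks at one checkpoint: N = best, 1 = worst.

    Ties are broken by child id (lower id ranks lower), so every rank in
    1..N is used exactly once.
    """
    scores = results.profile_at(epoch, measure)
    ids = scores.index.to_numpy()
    vals = scores.to_numpy()
    order = np.lexsort((ids, vals))          # ascending score, then id
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(ids) + 1)
    return pd.Series(ranks, index=ids, name=f"rank_{measure}_{epoch}")
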