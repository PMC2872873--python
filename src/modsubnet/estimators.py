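"""scikit-learn estimators wrapping subnetwork discovery and age prediction.

:class:`SubnetworkDiscovery` is a transformer: ``fit(X, y)`` takes a
sample x gene expression matrix and per-sample ages, grows scored subnetworks
on the supplied interaction network, optionally filters them by the two
permutation tests, and removes redundant results; ``transform(X)`` then maps
expression to per-sample subnetwork activities. Composed with
``sklearn.svm.SVR(kernel="linear")`` in a Pipeline it reproduces the full
subnetwork-biomarker age-prediction workflow and plays with sklearn model
selection out of the box.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionDataset, restrict_to_universe
from .prediction import SVR_C, SVR_EPSILON
from .scoring import weight_network
from .search import GrowthEngine, remove_redundant
from .significance import select_significant, significance_table

__all__ = ["SubnetworkDiscovery", "make_age_pipeline"]


class SubnetworkDiscovery(BaseEstimator, TransformerMixin):
    """Discover modular subnetworks and expose their activities as features.

    Parameters
    ----------
    network : networkx.Graph
        Undirected functional interaction network over gene identifiers.
        Weights are recomputed from the training expression at fit time.
    mode : {"modular", "regular"}
        Growth criterion: score S = R + beta*M, or pure relevance with a
        per-step gain threshold.
    beta : float
        Modularity coefficient (modular mode).
    r_threshold : float
        Minimum per-step relevance gain (regular mode).
    n_perm, n_interactomes : int
        Permutation counts for the self-contained and competitive tests. With
        both > 0 the full double filter is applied; with only ``n_perm`` > 0
        the self-contained test alone filters and ranks candidates (useful at
        small scale, where it is the component that removes age-irrelevant
        high-modularity candidates); with ``n_perm`` = 0 subnetworks are
        ranked by score alone.
    self_alpha, comp_alpha : float
        Significance thresholds for the two tests.
    max_overlap : float
        Jaccard threshold for redundancy removal.
    max_features : int or None
        Keep at most this many top-scoring subnetworks.
    min_size : int
        Smallest reported subnetwork (singletons excluded by default).
    random_state : int
        Seed for the permutation tests.

    Attributes
    ----------
    subnetworks_ : list of Subnetwork
        All grown subnetworks (one per seed).
    selected_ : list of Subnetwork
        Non-redundant (optionally significant) subnetworks used as features.
    universe_ : list of str
        Analyzable genes (largest connected component ∩ measured genes).
    feature_names_in_ : ndarray of gene identifiers seen at fit.
    """

    def __init__(
        self,
        network=None,
        mode: str = "modular",
        beta: float = 250.0,
        r_threshold: float = 0.05,
        n_perm: int = 0,
        n_interactomes: int = 0,
        self_alpha: float = 0.001,
        comp_alpha: float = 0.05,
        max_overlap: float = 0.25,
        max_features: int | None = None,
        min_size: int = 2,
        random_state: int = 0,
    ):
        self.network = network
        self.mode = mode
        self.beta = beta
        self.r_threshold = r_threshold
        self.n_perm = n_perm
        self.n_interactomes = n_interactomes
        self.self_alpha = self_alpha
        self.comp_alpha = comp_alpha
        self.max_overlap = max_overlap
        self.max_features = max_features
        self.min_size = min_size
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = np.array([f"g{i}" for i in range(X.shape[1])])
        return pd.DataFrame(X, columns=list(names))

    def fit(self, X, y):
        """Standardize genes, weight the network, grow and select subnetworks."""
        if self.network is None:
            raise ValueError("a network must be supplied")
        Xf = self._to_frame(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != Xf.shape[0]:
            raise ValueError("X and y have inconsistent sample counts")
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]

        self.gene_means_ = Xf.mean(axis=0)
        self.gene_stds_ = Xf.std(axis=0, ddof=0)
        usable = self.gene_stds_[self.gene_stds_ > 0].index
        Z = (Xf[usable] - self.gene_means_[usable]) / self.gene_stds_[usable]

        samples = [f"s{i}" for i in range(Z.shape[0])]
        values = pd.DataFrame(Z.to_numpy().T, index=list(usable), columns=samples)
        d = ExpressionDataset(values, pd.Series(y, index=samples, name="age"))
        g, d = restrict_to_universe(self.network, d)
        gw = weight_network(g, d)
        self.universe_ = sorted(gw.nodes)

        if self.n_perm > 0 and self.n_interactomes > 0:
            table, subs = significance_table(
                gw,
                d,
                mode=self.mode,
                beta=self.beta,
                r_threshold=self.r_threshold,
                n_perm=self.n_perm,
                n_interactomes=self.n_interactomes,
                rng_seed=self.random_state,
                self_alpha=self.self_alpha,
                comp_alpha=self.comp_alpha,
            )
            self.significance_ = table
            selected = select_significant(
                table,
                subs,
                self.self_alpha,
                self.comp_alpha,
                self.max_overlap,
                self.min_size,
            )
        elif self.n_perm > 0:
            from .significance import self_contained_test

            eng = GrowthEngine(gw, d)
            subs = eng.grow_all(
                mode=self.mode, beta=self.beta, r_threshold=self.r_threshold
            )
            selfp = self_contained_test(
                gw,
                d,
                mode=self.mode,
                beta=self.beta,
                r_threshold=self.r_threshold,
                n_perm=self.n_perm,
                rng_seed=self.random_state,
                engine=eng,
                true_subs=subs,
            )
            self.self_p_ = selfp
            passed = [
                s
                for s in subs
                if s.size >= self.min_size and selfp[s.seed] < self.self_alpha
            ]
            selected = remove_redundant(passed, max_overlap=self.max_overlap)
            selected.sort(key=lambda s: (selfp[s.seed], -s.score, s.seed))
        else:
            subs = GrowthEngine(gw, d).grow_all(
                mode=self.mode, beta=self.beta, r_threshold=self.r_threshold
            )
            selected = remove_redundant(
                [s for s in subs if s.size >= self.min_size],
                max_overlap=self.max_overlap,
            )
        self.subnetworks_ = subs
        if self.max_features is not None:
            selected = selected[: self.max_features]
        self.selected_ = selected
        return self

    def transform(self, X) -> np.ndarray:
        """Per-sample activity of every selected subnetwork."""
        check_is_fitted(self, "selected_")
        Xf = self._to_frame(X)
        if not self.selected_:
            raise ValueError("no subnetworks were selected at fit time")
        cols = []
        for sub in self.selected_:
            members = list(sub.members)
            z = (Xf[members] - self.gene_means_[members]) / self.gene_stds_[members]
            cols.append(z.to_numpy().mean(axis=1))
        return np.column_stack(cols)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "selected_")
        return np.asarray([s.seed for s in self.selected_], dtype=object)


def make_age_pipeline(network, **discovery_params) -> Pipeline:
    """Subnetwork discovery + linear-kernel epsilon-SVR in one sklearn Pipeline."""
    return Pipeline(
        [
            ("subnetworks", SubnetworkDiscovery(network=network, **discovery_params)),
            ("svr", SVR(kernel="linear", C=SVR_C, epsilon=SVR_EPSILON)),
        ]
    )
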