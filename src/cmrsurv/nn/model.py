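"""The three-branch multi-input risk network.

Branch 1 (cine): the 4D tensor (slices folded into channels, recurrence
over the cardiac-cycle axis) passes through a two-layer ConvLSTM encoder
whose final hidden state summarizes cardiac motion. Branch 2 (LGE): the
3D tensor passes through a small CNN encoder. The two image maps are
concatenated into a shared convolutional trunk, globally pooled, and
projected to a width-8 embedding. Branch 3 (covariates): two width-8
dense blocks produce a width-8 embedding. The image and covariate
embeddings are concatenated (width 16) and a dense head ends in a single
*linearly activated* node — the patient's log-relative-hazard.

After every learned layer the network applies batch normalization, an L2
activity penalty and dropout (each switchable in config), the standard
stabilizers for small-sample training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (
    ActivityL2,
    BatchNorm,
    Conv2D,
    ConvLSTM2D,
    Dense,
    Dropout,
    GlobalAvgPool2D,
    MaxPool2D,
    ReLU,
    Sequential,
    TimeDistributed,
)


@dataclass
class NetworkConfig:
    """Architecture and regularization defaults.

    Every number the method description leaves open lives here, not in
    code: two ConvLSTM layers (8 then 16 filters, 3x3), two LGE conv
    layers (8, 16), a two-layer shared trunk (16, 16) with 2x2 max-pooling,
    width-8 embeddings on both the image and covariate side, dropout 0.2
    and an L2 activity penalty of 1e-4 after every learned layer.
    ``covariates_only``/``linear_covariates`` collapse the model to a
    covariate branch (optionally a single linear unit, i.e. a plain Cox
    linear predictor trained by the same loss and optimizer).
    """

    cine_filters: tuple = (8, 16)
    lge_filters: tuple = (8, 16)
    trunk_filters: tuple = (16, 16)
    kernel: int = 3
    embed_dim: int = 8
    cov_hidden: tuple = (8, 8)
    head_hidden: int = 8
    dropout: float = 0.2
    activity_l2: float = 1e-4
    batchnorm: bool = True
    covariates_only: bool = False
    linear_covariates: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


class ConstructionError(ValueError):
    pass


class MultiInputCoxNet:
    """Maps (cine tensor, LGE tensor, covariate vector) to one log-risk scalar.

    Input spec: ``h``, ``w`` (even, for the pooling schedule), ``c`` =
    S + 3 channels (short-axis slices plus the three long-axis planes),
    ``t`` frames, ``n_cov`` encoded covariates. Batches are dicts with
    keys ``cine`` (N, T, C, H, W), ``lge`` (N, C, H, W), ``cov`` (N, p);
    covariate-only configs need only ``cov``.
    """

    def __init__(self, config: NetworkConfig, n_cov: int,
                 h: int = None, w: int = None, c: int = None, t: int = None):
        self.config = config
        self.n_cov = n_cov
        self.dims = dict(h=h, w=w, c=c, t=t)
        self.rng = np.random.default_rng(config.seed)
        self._build()

    # -- construction -----------------------------------------------------

    def _block(self, *layers):
        cfg = self.config
        out = []
        for layer in layers:
            out.append(layer)
            inner = layer.inner if isinstance(layer, TimeDistributed) else layer
            wrap = (lambda l: TimeDistributed(l)) if isinstance(layer, TimeDistributed) else (lambda l: l)
            n_feat = self._out_features(inner)
            if cfg.batchnorm and n_feat is not None:
                out.append(wrap(BatchNorm(n_feat)))
            if isinstance(inner, (Dense, Conv2D)):
                out.append(wrap(ReLU()))
            if cfg.activity_l2 > 0:
                out.append(wrap(ActivityL2(cfg.activity_l2)))
            if cfg.dropout > 0:
                out.append(wrap(Dropout(cfg.dropout)))
        return out

    @staticmethod
    def _out_features(layer):
        if isinstance(layer, Dense):
            return layer.params["w"].shape[1]
        if isinstance(layer, Conv2D):
            return layer.params["w"].shape[0]
        if isinstance(layer, ConvLSTM2D):
            return layer.f
        return None

    def _build(self):
        cfg = self.config
        rng = self.rng
        if cfg.covariates_only and cfg.linear_covariates:
            self.head = Sequential([Dense(self.n_cov, 1, rng)])
            self.cov_branch = self.cine_branch = self.lge_branch = self.trunk = None
            return

        self.cov_branch = Sequential(
            self._block(Dense(self.n_cov, cfg.cov_hidden[0], rng),
                        Dense(cfg.cov_hidden[0], cfg.cov_hidden[1], rng)))

        if cfg.covariates_only:
            self.cine_branch = self.lge_branch = self.trunk = None
            head_in = cfg.cov_hidden[1]
        else:
            h, w, c, t = (self.dims[k] for k in ("h", "w", "c", "t"))
            if None in (h, w, c, t):
                raise ConstructionError("image dims (h, w, c, t) required unless covariates_only")
            if h % 4 or w % 4:
                raise ConstructionError(
                    f"spatial dims must be divisible by 4 for the pooling schedule, got {(h, w)}")
            f1, f2 = cfg.cine_filters
            self.cine_branch = Sequential(
                [ConvLSTM2D(c, f1, cfg.kernel, rng, return_sequences=True)]
                + [TimeDistributed(BatchNorm(f1))] * cfg.batchnorm
                + ([TimeDistributed(ActivityL2(cfg.activity_l2))] if cfg.activity_l2 > 0 else [])
                + ([TimeDistributed(Dropout(cfg.dropout))] if cfg.dropout > 0 else [])
                + [ConvLSTM2D(f1, f2, cfg.kernel, rng, return_sequences=False)]
                + ([BatchNorm(f2)] if cfg.batchnorm else [])
                + ([ActivityL2(cfg.activity_l2)] if cfg.activity_l2 > 0 else [])
                + ([Dropout(cfg.dropout)] if cfg.dropout > 0 else []))
            g1, g2 = cfg.lge_filters
            self.lge_branch = Sequential(
                self._block(Conv2D(c, g1, cfg.kernel, rng),
                            Conv2D(g1, g2, cfg.kernel, rng)))
            t1, t2 = cfg.trunk_filters
            trunk_layers = (self._block(Conv2D(f2 + g2, t1, cfg.kernel, rng))
                            + [MaxPool2D()]
                            + self._block(Conv2D(t1, t2, cfg.kernel, rng))
                            + [MaxPool2D(), GlobalAvgPool2D()]
                            + self._block(Dense(t2, cfg.embed_dim, rng)))
            self.trunk = Sequential(trunk_layers)
            head_in = cfg.embed_dim + cfg.cov_hidden[1]

        self.head = Sequential(
            self._block(Dense(head_in, cfg.head_hidden, rng))
            + [Dense(cfg.head_hidden, 1, rng)])

    # -- execution --------------------------------------------------------

    def _branches(self):
        return [b for b in (self.cine_branch, self.lge_branch, self.trunk,
                            self.cov_branch, self.head) if b is not None]

    def forward(self, batch: dict, train: bool = False) -> np.ndarray:
        """One log-risk scalar per patient; deterministic in inference mode."""
        cfg = self.config
        rng = self.rng if train else None
        if cfg.covariates_only:
            x = np.asarray(batch["cov"], dtype=np.float64)
            if cfg.linear_covariates:
                return self.head.forward(x, train=train, rng=rng)[:, 0]
            h_cov = self.cov_branch.forward(x, train=train, rng=rng)
            self._head_split = None
            return self.head.forward(h_cov, train=train, rng=rng)[:, 0]

        cine = np.asarray(batch["cine"], dtype=np.float64)
        lge = np.asarray(batch["lge"], dtype=np.float64)
        cov = np.asarray(batch["cov"], dtype=np.float64)
        self._check_dims(cine, lge, cov)
        h_cine = self.cine_branch.forward(cine, train=train, rng=rng)
        h_lge = self.lge_branch.forward(lge, train=train, rng=rng)
        self._img_split = h_cine.shape[1]
        h_img = self.trunk.forward(np.concatenate([h_cine, h_lge], axis=1),
                                   train=train, rng=rng)
        h_cov = self.cov_branch.forward(cov, train=train, rng=rng)
        self._head_split = h_img.shape[1]
        merged = np.concatenate([h_img, h_cov], axis=1)
        return self.head.forward(merged, train=train, rng=rng)[:, 0]

    def backward(self, dscores: np.ndarray):
        """Backpropagate d(loss)/d(scores); fills every layer's grads."""
        cfg = self.config
        dout = np.asarray(dscores, dtype=np.float64)[:, None]
        dmerged = self.head.backward(dout)
        if cfg.covariates_only:
            if not cfg.linear_covariates:
                self.cov_branch.backward(dmerged)
            return
        d_img = dmerged[:, : self._head_split]
        d_cov = dmerged[:, self._head_split:]
        self.cov_branch.backward(d_cov)
        d_maps = self.trunk.backward(d_img)
        d_cine = d_maps[:, : self._img_split]
        d_lge = d_maps[:, self._img_split:]
        self.cine_branch.backward(d_cine)
        self.lge_branch.backward(d_lge)

    def penalty(self) -> float:
        """Total activity-regularization penalty from the last training pass."""
        return sum(b.penalty() for b in self._branches())

    def _check_dims(self, cine, lge, cov):
        h, w, c, t = (self.dims[k] for k in ("h", "w", "c", "t"))
        if cine.shape[1:] != (t, c, h, w):
            raise ConstructionError(
                f"cine batch shape {cine.shape[1:]} does not match the "
                f"homogenized dims the network was built for {(t, c, h, w)}")
        if lge.shape[1:] != (c, h, w):
            raise ConstructionError(
                f"lge batch shape {lge.shape[1:]} != {(c, h, w)}")
        if cov.shape[1] != self.n_cov:
            raise ConstructionError(f"covariate width {cov.shape[1]} != {self.n_cov}")

    # -- parameters -------------------------------------------------------

    def iter_params(self):
        for bi, branch in enumerate(self._branches()):
            for key, layer, name in branch.iter_params():
                yield f"b{bi}.{key}", layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for _, layer, name in self.iter_params())

    def get_weights(self) -> dict:
        weights = {key: layer.params[name].copy() for key, layer, name in self.iter_params()}
        for bi, branch in enumerate(self._branches()):
            for i, lay in enumerate(branch.layers):
                inner = lay.inner if isinstance(lay, TimeDistributed) else lay
                if isinstance(inner, BatchNorm):
                    weights[f"b{bi}.{i}.running_mean"] = inner.running_mean.copy()
                    weights[f"b{bi}.{i}.running_var"] = inner.running_var.copy()
        return weights

    def set_weights(self, weights: dict):
        for key, layer, name in self.iter_params():
            layer.params[name] = weights[key].copy()
        for bi, branch in enumerate(self._branches()):
            for i, lay in enumerate(branch.layers):
                inner = lay.inner if isinstance(lay, TimeDistributed) else lay
                if isinstance(inner, BatchNorm):
                    inner.running_mean = weights[f"b{bi}.{i}.running_mean"].copy()
                    inner.running_var = weights[f"b{bi}.{i}.running_var"].copy()
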