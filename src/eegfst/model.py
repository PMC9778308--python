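"""The frequency-spatial-temporal network: a depthwise-separable CNN shared
across time slices, an ordered-neuron LSTM over the slice sequence, and a
softmax head.

Per time slice the CNN sees an (bands, grid_h, grid_w) feature map and
produces a fixed-width embedding, so a 4D sample of 2T slices becomes a
matrix Q of shape (dense_units, 2T).  The ON-LSTM consumes the 2T columns
in order.  Its distinguishing feature is a pair of *master* gates obtained
by cumulative sums of softmax outputs:

    f~_t = cumsum_left ( softmax(W_mf q_t + U_mf h_{t-1} + b_mf) )
    i~_t = cumsum_right( softmax(W_mi q_t + U_mi h_{t-1} + b_mi) )
    w_t  = f~_t * i~_t

f~ is non-decreasing along the hidden axis and ends at 1, i~ is
non-increasing and starts at 1; their product marks the overlap region of
hidden units that updates LSTM-style, while units above the overlap copy
history and units below copy fresh input — imposing an ordering (hierarchy)
on the hidden state.  Two cell-update variants are provided:

    as_printed: c_t = w*(f*c_{t-1} + i~*c^) + (f~-w)*c_{t-1} + (i~-w)*c^
    canonical:  c_t = w*(f*c_{t-1} + i *c^) + (f~-w)*c_{t-1} + (i~-w)*c^

which differ only in which input gate modulates the overlap term; clamping
both master gates to 1 reduces the canonical variant to the standard LSTM
update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .features import Sample4D
from .nn import BatchNormState, Tensor

__all__ = [
    "CNNConfig",
    "ONLSTMParams",
    "HeadParams",
    "FSTception",
    "cnn_forward",
    "onlstm_step",
    "onlstm_gates",
    "onlstm_sequence",
    "classify",
    "conv_param_count",
    "onlstm_param_count",
    "count_parameters",
]


@dataclass(frozen=True)
class CNNConfig:
    """Widths and kernel sizes of the per-slice CNN.

    The defaults follow the full-size architecture: a 1x1/64 convolution, a
    3x3/128 convolution, a 3x3 depthwise convolution, a separable
    convolution (3x3 depthwise + 1x1 pointwise to 256 maps), each with zero
    ("same") padding, batch normalization and ReLU, then 2x2/stride-2 max
    pooling and a 512-unit fully connected layer.
    """

    conv1_filters: int = 64
    conv1_kernel: int = 1
    conv2_filters: int = 128
    conv2_kernel: int = 3
    depthwise_kernel: int = 3
    separable_kernel: int = 3
    pointwise_filters: int = 256
    pool: int = 2
    dense_units: int = 512
    grid_h: int = 8
    grid_w: int = 9
    n_bands: int = 5

    def __post_init__(self) -> None:
        for name in ("conv1_filters", "conv2_filters", "pointwise_filters",
                     "dense_units", "grid_h", "grid_w", "n_bands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.pool != 2:
            raise ValueError("only 2x2/stride-2 pooling is supported")

    @property
    def pooled_shape(self) -> Tuple[int, int]:
        # odd extents are -inf padded before pooling, i.e. ceil division
        return (-(-self.grid_h // 2), -(-self.grid_w // 2))

    @property
    def flat_features(self) -> int:
        ph, pw = self.pooled_shape
        return ph * pw * self.pointwise_filters

    @staticmethod
    def reduced(grid_h: int = 8, grid_w: int = 9, n_bands: int = 5) -> "CNNConfig":
        """Half-width variant for desk-scale experiments."""
        return CNNConfig(
            conv1_filters=32,
            conv2_filters=64,
            pointwise_filters=128,
            dense_units=256,
            grid_h=grid_h,
            grid_w=grid_w,
            n_bands=n_bands,
        )


def _he(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _xavier(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


_GATES = ("f", "i", "o", "c", "mf", "mi")


@dataclass
class ONLSTMParams:
    """Weights of one ordered-neuron LSTM layer.

    Six gates (forget, input, output, candidate, master-forget,
    master-input), each with an input matrix W (input_size x out), a
    recurrent matrix U (hidden x out) and a bias.  Master gates act at
    resolution ``hidden // chunk`` and are expanded by repetition.
    """

    input_size: int = 512
    hidden: int = 128
    chunk: int = 1
    variant: str = "as_printed"
    W: Dict[str, Tensor] = field(default_factory=dict)
    U: Dict[str, Tensor] = field(default_factory=dict)
    b: Dict[str, Tensor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hidden % self.chunk != 0:
            raise ValueError("chunk factor must divide the hidden size")
        if self.variant not in ("as_printed", "canonical"):
            raise ValueError("variant must be 'as_printed' or 'canonical'")
        if not self.W:
            self._init_zeros()

    @property
    def master_size(self) -> int:
        return self.hidden // self.chunk

    def _gate_out(self, g: str) -> int:
        return self.master_size if g in ("mf", "mi") else self.hidden

    def _init_zeros(self) -> None:
        for g in _GATES:
            out = self._gate_out(g)
            self.W[g] = nn.parameter(np.zeros((self.input_size, out)))
            self.U[g] = nn.parameter(np.zeros((self.hidden, out)))
            self.b[g] = nn.parameter(np.zeros(out))

    @staticmethod
    def init(
        input_size: int,
        hidden: int = 128,
        chunk: int = 1,
        variant: str = "as_printed",
        rng: Optional[np.random.Generator] = None,
    ) -> "ONLSTMParams":
        """Xavier-initialized weights; forget-gate bias starts at 1."""
        rng = rng or np.random.default_rng(0)
        p = ONLSTMParams(input_size=input_size, hidden=hidden, chunk=chunk, variant=variant)
        for g in _GATES:
            out = p._gate_out(g)
            p.W[g] = nn.parameter(_xavier(rng, (input_size, out)))
            p.U[g] = nn.parameter(_xavier(rng, (hidden, out)))
            bias = np.zeros(out)
            if g == "f":
                bias += 1.0
            p.b[g] = nn.parameter(bias)
        return p

    def parameters(self) -> List[Tensor]:
        return [t for d in (self.W, self.U, self.b) for t in d.values()]


@dataclass
class HeadParams:
    """Softmax head: logits = A y + b over ``n_classes`` categories."""

    hidden: int = 128
    n_classes: int = 2
    A: Tensor = None  # (hidden, n_classes)
    bias: Tensor = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.A is None:
            self.A = nn.parameter(np.zeros((self.hidden, self.n_classes)))
        if self.bias is None:
            self.bias = nn.parameter(np.zeros(self.n_classes))

    @staticmethod
    def init(hidden: int, n_classes: int, rng: np.random.Generator) -> "HeadParams":
        return HeadParams(
            hidden=hidden,
            n_classes=n_classes,
            A=nn.parameter(_xavier(rng, (hidden, n_classes))),
            bias=nn.parameter(np.zeros(n_classes)),
        )

    def parameters(self) -> List[Tensor]:
        return [self.A, self.bias]


# ---------------------------------------------------------------------------
# ON-LSTM cell
# ---------------------------------------------------------------------------

def _expand_master(g: Tensor, chunk: int) -> Tensor:
    """Repeat each master-gate component ``chunk`` times along the hidden axis."""
    if chunk == 1:
        return g
    b, dm = g.shape
    g3 = nn.reshape(g, (b, dm, 1))
    ones = Tensor(np.ones((1, 1, chunk), dtype=np.float32))
    return nn.reshape(nn.mul(g3, ones), (b, dm * chunk))


def _gate_pre(q: Tensor, h: Tensor, p: ONLSTMParams, g: str) -> Tensor:
    return nn.add(nn.add(nn.matmul(q, p.W[g]), nn.matmul(h, p.U[g])), p.b[g])


def _onlstm_step_t(
    q: Tensor,
    h_prev: Tensor,
    c_prev: Tensor,
    p: ONLSTMParams,
    clamp_master: bool = False,
) -> Tuple[Tensor, Tensor, Dict[str, Tensor]]:
    """One ON-LSTM step on batched Tensors; returns (h_t, c_t, gates)."""
    f = nn.sigmoid(_gate_pre(q, h_prev, p, "f"))
    i = nn.sigmoid(_gate_pre(q, h_prev, p, "i"))
    o = nn.sigmoid(_gate_pre(q, h_prev, p, "o"))
    chat = nn.tanh(_gate_pre(q, h_prev, p, "c"))
    if clamp_master:
        mf = Tensor(np.ones((q.shape[0], p.hidden), dtype=np.float32))
        mi = Tensor(np.ones((q.shape[0], p.hidden), dtype=np.float32))
    else:
        mf = nn.cumsum(nn.softmax(_gate_pre(q, h_prev, p, "mf"), axis=-1), axis=-1)
        mi = nn.cumsum(nn.softmax(_gate_pre(q, h_prev, p, "mi"), axis=-1), axis=-1,
                       reverse=True)
        mf = _expand_master(mf, p.chunk)
        mi = _expand_master(mi, p.chunk)
    w = nn.mul(mf, mi)
    overlap_input = i if p.variant == "canonical" else mi
    inner = nn.add(nn.mul(f, c_prev), nn.mul(overlap_input, chat))
    c = nn.add(
        nn.mul(w, inner),
        nn.add(nn.mul(nn.sub(mf, w), c_prev), nn.mul(nn.sub(mi, w), chat)),
    )
    h = nn.mul(o, nn.tanh(c))
    gates = {"f": f, "i": i, "o": o, "chat": chat, "mf": mf, "mi": mi, "w": w}
    return h, c, gates


def _as_batch(v: np.ndarray) -> Tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=np.float32)
    if v.ndim == 1:
        return v[None, :], True
    return v, False


def onlstm_step(
    q_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: ONLSTMParams,
    clamp_master: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """One ON-LSTM step on numpy inputs (single vectors or batches)."""
    for name, v in (("q_t", q_t), ("h_prev", h_prev), ("c_prev", c_prev)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} contains non-finite values")
    q, was_vec = _as_batch(q_t)
    h0, _ = _as_batch(h_prev)
    c0, _ = _as_batch(c_prev)
    h, c, _ = _onlstm_step_t(Tensor(q), Tensor(h0), Tensor(c0), params,
                             clamp_master=clamp_master)
    if was_vec:
        return h.data[0], c.data[0]
    return h.data, c.data


def onlstm_gates(
    q_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: ONLSTMParams
) -> Dict[str, np.ndarray]:
    """Gate activations of one step (for inspection and testing)."""
    q, was_vec = _as_batch(q_t)
    h0, _ = _as_batch(h_prev)
    c0, _ = _as_batch(c_prev)
    _, _, gates = _onlstm_step_t(Tensor(q), Tensor(h0), Tensor(c0), params)
    out = {k: v.data for k, v in gates.items()}
    if was_vec:
        out = {k: v[0] for k, v in out.items()}
    return out


def onlstm_sequence(Q: np.ndarray, params: ONLSTMParams) -> np.ndarray:
    """Run the cell over the columns of ``Q`` (input_size x 2T); return h_{2T}.

    The initial hidden and cell states are zero.
    """
    Q = np.asarray(Q, dtype=np.float32)
    if Q.ndim != 2 or Q.shape[1] < 1:
        raise ValueError("Q must be (input_size, 2T) with 2T >= 1")
    h = np.zeros(params.hidden, dtype=np.float32)
    c = np.zeros(params.hidden, dtype=np.float32)
    for t in range(Q.shape[1]):
        h, c = onlstm_step(Q[:, t], h, c, params)
    return h


def classify(y: np.ndarray, head: HeadParams) -> np.ndarray:
    """Softmax class probabilities from the final ON-LSTM state."""
    y = np.asarray(y, dtype=np.float64)
    out = y @ head.A.data.astype(np.float64) + head.bias.data.astype(np.float64)
    z = out - out.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class FSTception:
    """Per-slice depthwise-separable CNN + ON-LSTM + softmax head."""

    def __init__(
        self,
        cnn: CNNConfig = CNNConfig(),
        hidden: int = 128,
        n_classes: int = 2,
        chunk: int = 1,
        variant: str = "as_printed",
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.cnn = cnn
        self.training = True

        c1, c2 = cnn.conv1_filters, cnn.conv2_filters
        k1, k2 = cnn.conv1_kernel, cnn.conv2_kernel
        kd, ks = cnn.depthwise_kernel, cnn.separable_kernel
        pw = cnn.pointwise_filters
        a = cnn.n_bands

        self.w1 = nn.parameter(_he(rng, (k1, k1, a, c1), a * k1 * k1))
        self.b1 = nn.parameter(np.zeros(c1))
        self.bn1 = self._bn(c1)
        self.w2 = nn.parameter(_he(rng, (k2, k2, c1, c2), c1 * k2 * k2))
        self.b2 = nn.parameter(np.zeros(c2))
        self.bn2 = self._bn(c2)
        self.wd = nn.parameter(_he(rng, (kd, kd, c2), kd * kd))
        self.bd = nn.parameter(np.zeros(c2))
        self.bnd = self._bn(c2)
        self.wsd = nn.parameter(_he(rng, (ks, ks, c2), ks * ks))
        self.bsd = nn.parameter(np.zeros(c2))
        self.wsp = nn.parameter(_he(rng, (1, 1, c2, pw), c2))
        self.bsp = nn.parameter(np.zeros(pw))
        self.bns = self._bn(pw)
        self.wfc = nn.parameter(_he(rng, (cnn.flat_features, cnn.dense_units),
                                    cnn.flat_features))
        self.bfc = nn.parameter(np.zeros(cnn.dense_units))
        self.bnf = self._bn(cnn.dense_units)

        self.onlstm = ONLSTMParams.init(cnn.dense_units, hidden, chunk, variant, rng)
        self.head = HeadParams.init(hidden, n_classes, rng)

    def _bn(self, n: int) -> Tuple[Tensor, Tensor, BatchNormState]:
        return (nn.parameter(np.ones(n)), nn.parameter(np.zeros(n)), BatchNormState(n))

    def parameters(self) -> List[Tensor]:
        conv = [
            self.w1, self.b1, self.w2, self.b2, self.wd, self.bd,
            self.wsd, self.bsd, self.wsp, self.bsp, self.wfc, self.bfc,
        ]
        for g, b, _ in (self.bn1, self.bn2, self.bnd, self.bns, self.bnf):
            conv += [g, b]
        return conv + self.onlstm.parameters() + self.head.parameters()

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    # -- forward ------------------------------------------------------------

    def _slice_cnn(self, x: Tensor) -> Tensor:
        """(N, h, w, bands) slice batch -> (N, dense_units) embeddings."""
        g1, be1, st1 = self.bn1
        g2, be2, st2 = self.bn2
        gd, bed, std_ = self.bnd
        gs, bes, sts = self.bns
        y = nn.relu(nn.batchnorm(nn.conv2d(x, self.w1, self.b1), g1, be1, st1, self.training))
        y = nn.relu(nn.batchnorm(nn.conv2d(y, self.w2, self.b2), g2, be2, st2, self.training))
        y = nn.relu(nn.batchnorm(nn.depthwise_conv2d(y, self.wd, self.bd), gd, bed, std_, self.training))
        y = nn.depthwise_conv2d(y, self.wsd, self.bsd)
        y = nn.conv2d(y, self.wsp, self.bsp)
        y = nn.relu(nn.batchnorm(y, gs, bes, sts, self.training))
        y = nn.maxpool2x2(y)
        n = y.shape[0]
        y = nn.reshape(y, (n, self.cnn.flat_features))
        gf, bef, stf = self.bnf
        # the dense layer is normalized like the convolutional layers: a
        # fully dead ReLU layer would zero all gradients permanently, and
        # batch norm keeps the pre-activations centred
        return nn.relu(nn.batchnorm(nn.dense(y, self.wfc, self.bfc), gf, bef, stf,
                                    self.training))

    def forward(self, x: np.ndarray) -> Tensor:
        """Batch forward: ``x`` is (B, h, w, bands, 2T); returns logits (B, c)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError("expected a batch of 4D samples: (B, h, w, bands, 2T)")
        b, h, w, a, two_t = x.shape
        if (h, w, a) != (self.cnn.grid_h, self.cnn.grid_w, self.cnn.n_bands):
            raise ValueError(
                f"sample slices are {(h, w, a)}, model expects "
                f"{(self.cnn.grid_h, self.cnn.grid_w, self.cnn.n_bands)}"
            )
        # (B, 2T, h, w, bands) -> fold slices into the batch: shared weights
        slices = np.ascontiguousarray(x.transpose(0, 4, 1, 2, 3)).reshape(
            b * two_t, h, w, a
        )
        q = self._slice_cnn(Tensor(slices))  # (B*2T, dense)
        q = nn.reshape(q, (b, two_t, self.cnn.dense_units))
        hs = Tensor(np.zeros((b, self.onlstm.hidden), dtype=np.float32))
        cs = Tensor(np.zeros((b, self.onlstm.hidden), dtype=np.float32))
        for t in range(two_t):
            hs, cs, _ = _onlstm_step_t(q[:, t, :], hs, cs, self.onlstm)
        return nn.dense(hs, self.head.A, self.head.bias)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            outs = []
            for i in range(0, len(x), batch_size):
                logits = self.forward(x[i : i + batch_size]).data.astype(np.float64)
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
            return np.concatenate(outs)
        finally:
            self.training = was_training

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def cnn_forward(sample: "Sample4D | np.ndarray", model: FSTception) -> np.ndarray:
    """Per-slice CNN embeddings of one sample: (dense_units, 2T).

    The same weights are applied to every time slice independently; column t
    is the embedding of slice t.  Runs in evaluation mode.
    """
    tensor = sample.tensor if isinstance(sample, Sample4D) else np.asarray(sample)
    if tensor.ndim != 4:
        raise ValueError("expected one 4D sample (h, w, bands, 2T)")
    h, w, a, two_t = tensor.shape
    if (h, w, a) != (model.cnn.grid_h, model.cnn.grid_w, model.cnn.n_bands):
        raise ValueError(
            f"sample slices are {(h, w, a)}, model expects "
            f"{(model.cnn.grid_h, model.cnn.grid_w, model.cnn.n_bands)}"
        )
    was_training = model.training
    model.eval()
    try:
        slices = np.ascontiguousarray(
            tensor.transpose(3, 0, 1, 2).astype(np.float32)
        )  # (2T, h, w, bands)
        q = model._slice_cnn(Tensor(slices)).data  # (2T, dense)
    finally:
        model.training = was_training
    return q.T


# ---------------------------------------------------------------------------
# parameter / FLOP accounting
# ---------------------------------------------------------------------------

def conv_param_count(c_in: int, c_out: int, kernel: int, bias: bool = True) -> int:
    """Trainable parameters of a full convolution layer."""
    return kernel * kernel * c_in * c_out + (c_out if bias else 0)


def onlstm_param_count(input_size: int, hidden: int, chunk: int = 1) -> int:
    """Trainable parameters of the six-gate ordered-neuron cell."""
    dm = hidden // chunk
    full = 4 * (input_size * hidden + hidden * hidden + hidden)
    master = 2 * (input_size * dm + hidden * dm + dm)
    return full + master


def count_parameters(
    cnn: CNNConfig,
    onlstm: ONLSTMParams,
    head: HeadParams,
    two_t: int = 6,
    include_batchnorm: bool = True,
) -> Tuple[int, float]:
    """Exact trainable-parameter count and forward-pass FLOP estimate.

    FLOPs count one multiply-accumulate as two floating operations for one
    sample (all 2T slices plus the recurrent and head stages).
    """
    h, w = cnn.grid_h, cnn.grid_w
    c1, c2, pw = cnn.conv1_filters, cnn.conv2_filters, cnn.pointwise_filters
    params = 0
    params += conv_param_count(cnn.n_bands, c1, cnn.conv1_kernel)
    params += conv_param_count(c1, c2, cnn.conv2_kernel)
    params += cnn.depthwise_kernel ** 2 * c2 + c2          # depthwise
    params += cnn.separable_kernel ** 2 * c2 + c2          # separable, depthwise part
    params += conv_param_count(c2, pw, 1)                  # separable, pointwise part
    params += cnn.flat_features * cnn.dense_units + cnn.dense_units
    if include_batchnorm:
        params += 2 * (c1 + c2 + c2 + pw + cnn.dense_units)
    params += onlstm_param_count(onlstm.input_size, onlstm.hidden, onlstm.chunk)
    params += head.hidden * head.n_classes + head.n_classes

    hw = h * w
    macs_slice = (
        hw * cnn.conv1_kernel ** 2 * cnn.n_bands * c1
        + hw * cnn.conv2_kernel ** 2 * c1 * c2
        + hw * cnn.depthwise_kernel ** 2 * c2
        + hw * cnn.separable_kernel ** 2 * c2
        + hw * c2 * pw
        + cnn.flat_features * cnn.dense_units
    )
    dm = onlstm.hidden // onlstm.chunk
    macs_step = (
        4 * (onlstm.input_size * onlstm.hidden + onlstm.hidden ** 2)
        + 2 * (onlstm.input_size * dm + onlstm.hidden * dm)
    )
    macs = two_t * (macs_slice + macs_step) + head.hidden * head.n_classes
    return params, 2.0 * macs
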