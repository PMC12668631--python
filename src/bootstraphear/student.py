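"""The Student: a fully-connected ReLU localiser network and its optimiser.

The Student maps the 48-dimensional binaural magnitude vector to azimuth
(and optionally elevation) in degrees through 5 hidden layers of 128
rectified units and a linear output.  It is the only plastic component of
the agent; training signals arrive as externally assembled gradients (the
surrogate-gradient and policy-gradient procedures in
:mod:`bootstraphear.learning`), which are applied with the Adam optimiser
(alpha=0.001, beta1=0.9, beta2=0.999, eps=1e-8, batch size 32).

Hidden weights are He-normal initialized, Normal(0, sqrt(2/fan_in)); the
output layer uses a 100x smaller scale so that initial predictions
concentrate near 0 degrees (the midline), matching the behaviour of an
untrained localiser that defaults to "straight ahead".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OUTPUT_INIT_FACTOR = 0.01


class StudentNet:
    """Weights and biases of the localiser MLP.

    ``weights[i]`` has shape (fan_in, fan_out); forward is x @ W + b with
    ReLU on all but the last layer.  All parameters live in one flat
    buffer (``flat``); ``weights``/``biases`` are reshaped views into it,
    which keeps the optimiser a few whole-vector operations.
    """

    def __init__(self, weights, biases, input_offset: float = 0.0,
                 input_scale: float = 1.0, dtype=np.float64):
        sizes = [w.size for pair in zip(weights, biases) for w in pair]
        self.flat = np.empty(sum(sizes), dtype=dtype)
        self.weights, self.biases = [], []
        offset = 0
        for w, b in zip(weights, biases):
            wv = self.flat[offset:offset + w.size].reshape(w.shape)
            wv[...] = w
            offset += w.size
            bv = self.flat[offset:offset + b.size].reshape(b.shape)
            bv[...] = b
            offset += b.size
            self.weights.append(wv)
            self.biases.append(bv)
        # fixed affine input stage: (x - offset) / scale.  The ANF magnitude
        # scale is arbitrary, so the network standardizes its input once at
        # construction (nominal stimulus level and a fixed 20 dB unit for
        # acoustic inputs); this is part of the network, not the environment.
        self.input_offset = float(input_offset)
        self.input_scale = float(input_scale)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]

    def parameters(self):
        for w, b in zip(self.weights, self.biases):
            yield w
            yield b

    @property
    def dtype(self):
        return self.flat.dtype

    def copy(self) -> "StudentNet":
        return StudentNet(self.weights, self.biases,
                          self.input_offset, self.input_scale, self.dtype)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray):
        """Forward pass returning output and the cache needed for backward."""
        x = np.atleast_2d(np.asarray(x, dtype=self.flat.dtype))
        if self.input_offset != 0.0 or self.input_scale != 1.0:
            x = (x - self.input_offset) / self.input_scale
        activations = [x]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = activations[-1] @ w + b
            if i < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            activations.append(z)
        return activations[-1], activations

    def _ensure_grad_buffer(self):
        if not hasattr(self, "_gflat"):
            self._gflat = np.zeros_like(self.flat)
            self._gw, self._gb = [], []
            offset = 0
            for w, b in zip(self.weights, self.biases):
                self._gw.append(
                    self._gflat[offset:offset + w.size].reshape(w.shape))
                offset += w.size
                self._gb.append(
                    self._gflat[offset:offset + b.size].reshape(b.shape))
                offset += b.size

    def backward(self, activations, grad_out: np.ndarray, reuse_buffer=False):
        """Backpropagate d(loss)/d(output) to parameter gradients.

        ``grad_out`` has shape (batch, output_dim); gradients are averaged
        over the batch (matching a mean-reduction loss).  With
        ``reuse_buffer=True`` the gradients are written into a persistent
        internal buffer (overwritten on the next such call), which the
        optimiser consumes without copying.
        """
        batch = activations[0].shape[0]
        if reuse_buffer:
            self._ensure_grad_buffer()
            grads_w, grads_b = self._gw, self._gb
        else:
            grads_w = [np.empty_like(w) for w in self.weights]
            grads_b = [np.empty_like(b) for b in self.biases]
        delta = np.asarray(grad_out, dtype=self.flat.dtype) / batch
        for i in reversed(range(len(self.weights))):
            np.matmul(activations[i].T, delta, out=grads_w[i])
            delta.sum(axis=0, out=grads_b[i])
            if i > 0:
                delta = (delta @ self.weights[i].T) * (activations[i] > 0.0)
        return grads_w, grads_b

    def save(self, path) -> None:
        """Checkpoint the weights with a manifest of layer shapes."""
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        arrays["layer_sizes"] = np.array(self.layer_sizes)
        arrays["input_affine"] = np.array([self.input_offset,
                                           self.input_scale])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "StudentNet":
        data = np.load(path)
        n = sum(1 for k in data.files if k.startswith("w"))
        offset, scale = data.get("input_affine", np.array([0.0, 1.0]))
        return cls([data[f"w{i}"] for i in range(n)],
                   [data[f"b{i}"] for i in range(n)], offset, scale,
                   dtype=data["w0"].dtype)


ACOUSTIC_INPUT_OFFSET = 70.0  # nominal stimulus level, dB SPL
ACOUSTIC_INPUT_SCALE = 20.0   # one level-jitter unit, dB


def init_student(rng: np.random.Generator, input_dim: int = 48,
                 output_dim: int = 1, hidden: int = 128,
                 n_hidden_layers: int = 5, input_offset: float = 0.0,
                 input_scale: float = 1.0, dtype=np.float64) -> StudentNet:
    """He-normal initialisation with a near-midline output layer."""
    sizes = [input_dim] + [hidden] * n_hidden_layers + [output_dim]
    weights, biases = [], []
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / fan_in)
        if i == len(sizes) - 2:
            scale *= OUTPUT_INIT_FACTOR
        weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
        biases.append(np.zeros(fan_out))
    return StudentNet(weights, biases, input_offset, input_scale, dtype)


def init_acoustic_student(rng: np.random.Generator, input_dim: int = 48,
                          output_dim: int = 1) -> StudentNet:
    """A localiser Student with the standard acoustic input standardization.

    Uses single precision: interactive training is throughput-bound and the
    binary teaching signal carries far less precision than float32.
    """
    return init_student(rng, input_dim, output_dim,
                        input_offset=ACOUSTIC_INPUT_OFFSET,
                        input_scale=ACOUSTIC_INPUT_SCALE, dtype=np.float32)


def predict(net: StudentNet, x: np.ndarray) -> np.ndarray:
    """Network prediction in degrees, wrapped/clipped at the interface.

    Azimuth (first output) is wrapped onto [-180, 180); a second output, if
    present, is elevation and is clipped to the spherical cap [-40, 90].
    Shape (batch, output_dim), or (output_dim,) for a single input.
    """
    from .angles import clip_elevation, wrap_deg

    squeeze = np.ndim(x) == 1
    out, _ = net.forward(x)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite student prediction")
    out = out.copy()
    out[:, 0] = wrap_deg(out[:, 0])
    if out.shape[1] > 1:
        out[:, 1] = clip_elevation(out[:, 1])
    return out[0] if squeeze else out


@dataclass
class AdamState:
    """First/second moment accumulators and step counter for Adam."""

    m: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t: int = 0
    alpha: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def for_net(cls, net: StudentNet, alpha: float = 1e-3) -> "AdamState":
        return cls(m=np.zeros_like(net.flat), v=np.zeros_like(net.flat),
                   alpha=alpha)


def adam_step(net: StudentNet, grads_w, grads_b, state: AdamState,
              lr: float | None = None) -> None:
    """One Adam update in place; ``lr`` overrides the stored alpha (schedules)."""
    if grads_w is getattr(net, "_gw", None):
        g = net._gflat
    else:
        pieces = []
        for gw, gb in zip(grads_w, grads_b):
            pieces.append(np.ravel(gw))
            pieces.append(np.ravel(gb))
        g = np.concatenate(pieces)
        if g.dtype != net.flat.dtype:
            g = g.astype(net.flat.dtype)
    if not np.isfinite(float(g.sum())):
        raise FloatingPointError("non-finite gradient passed to Adam")
    lr = state.alpha if lr is None else lr
    state.t += 1
    b1t = 1.0 - state.beta1 ** state.t
    b2t = 1.0 - state.beta2 ** state.t
    m, v = state.m, state.v
    m *= state.beta1
    m += (1.0 - state.beta1) * g
    v *= state.beta2
    g *= g
    v += (1.0 - state.beta2) * g
    # standard bias-corrected update: p -= lr * (m/b1t) / (sqrt(v/b2t) + eps)
    denom = np.sqrt(v)
    denom /= np.sqrt(b2t)
    denom += state.eps
    np.divide(m, denom, out=denom)
    denom *= lr / b1t
    net.flat -= denom


class StudentEnsemble:
    """A stack of independently initialized localiser networks.

    All members share one architecture; parameters live in a (k, P) float32
    block and the forward/backward passes run as batched matrix products,
    so training k students costs little more than training one.  Members
    are mathematically identical to individually trained
    :class:`StudentNet` instances (each sees its own episodes and its own
    Adam state); ``member(i)`` extracts a standalone net.
    """

    def __init__(self, nets: list):
        ref = nets[0]
        self.input_offset = ref.input_offset
        self.input_scale = ref.input_scale
        self.k = len(nets)
        self.flat = np.stack([n.flat for n in nets]).astype(np.float32)
        self._shapes = [(w.shape, b.shape)
                        for w, b in zip(ref.weights, ref.biases)]
        self.weights, self.biases = [], []
        offset = 0
        for wshape, bshape in self._shapes:
            wsize = int(np.prod(wshape))
            self.weights.append(
                self.flat[:, offset:offset + wsize].reshape((self.k,) + wshape))
            offset += wsize
            bsize = int(np.prod(bshape))
            self.biases.append(
                self.flat[:, offset:offset + bsize].reshape((self.k,) + bshape))
            offset += bsize
        self._gflat = np.zeros_like(self.flat)
        self._gw, self._gb = [], []
        offset = 0
        for wshape, bshape in self._shapes:
            wsize = int(np.prod(wshape))
            self._gw.append(
                self._gflat[:, offset:offset + wsize].reshape(
                    (self.k,) + wshape))
            offset += wsize
            bsize = int(np.prod(bshape))
            self._gb.append(
                self._gflat[:, offset:offset + bsize].reshape(
                    (self.k,) + bshape))
            offset += bsize

    @classmethod
    def acoustic(cls, seeds, input_dim: int = 48, output_dim: int = 1
                 ) -> "StudentEnsemble":
        nets = [init_acoustic_student(np.random.default_rng(s), input_dim,
                                      output_dim) for s in seeds]
        return cls(nets)

    def member(self, i: int) -> StudentNet:
        return StudentNet([w[i] for w in self.weights],
                          [b[i] for b in self.biases],
                          self.input_offset, self.input_scale,
                          dtype=np.float32)

    def forward(self, x: np.ndarray):
        """Batched forward: x of shape (k, batch, input_dim)."""
        x = np.asarray(x, dtype=np.float32)
        if self.input_offset != 0.0 or self.input_scale != 1.0:
            x = (x - self.input_offset) / self.input_scale
        activations = [x]
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = activations[-1] @ w + b[:, None, :]
            if i < last:
                z = np.maximum(z, 0.0)
            activations.append(z)
        return activations[-1], activations

    def backward(self, activations, grad_out: np.ndarray):
        """Batched backward; returns the (k, P) gradient block."""
        batch = activations[0].shape[1]
        delta = np.asarray(grad_out, dtype=np.float32) / batch
        for i in reversed(range(len(self.weights))):
            np.matmul(activations[i].transpose(0, 2, 1), delta,
                      out=self._gw[i])
            delta.sum(axis=1, out=self._gb[i])
            if i > 0:
                delta = (delta @ self.weights[i].transpose(0, 2, 1)) \
                    * (activations[i] > 0.0)
        return self._gflat


def _adam_fused_kernel():
    """Build (once) a fused single-pass Adam kernel with numba."""
    import numba

    @numba.njit(fastmath=True, cache=False)
    def kernel(p, g, m, v, b1, b2, scale, root, eps):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            mi = b1 * m[i] + (1.0 - b1) * gi
            vi = b2 * v[i] + (1.0 - b2) * gi * gi
            m[i] = mi
            v[i] = vi
            p[i] -= scale * mi / (np.sqrt(vi) / root + eps)

    return kernel


_ADAM_KERNEL = None


def adam_step_ensemble(ens: StudentEnsemble, grad: np.ndarray,
                       state: AdamState, lr: float | None = None) -> None:
    """Adam on the stacked (k, P) parameter block (per-parameter moments).

    The update is the standard bias-corrected rule, executed as one fused
    pass over the block (the stacked moments exceed cache, so the usual
    expression-at-a-time evaluation is memory-bound).
    """
    global _ADAM_KERNEL
    if not np.isfinite(float(grad.sum())):
        raise FloatingPointError("non-finite gradient passed to Adam")
    lr = state.alpha if lr is None else lr
    state.t += 1
    b1t = 1.0 - state.beta1 ** state.t
    b2t = 1.0 - state.beta2 ** state.t
    if _ADAM_KERNEL is None:
        _ADAM_KERNEL = _adam_fused_kernel()
    _ADAM_KERNEL(ens.flat.ravel(), np.ravel(grad), state.m.ravel(),
                 state.v.ravel(), state.beta1, state.beta2,
                 lr / b1t, float(np.sqrt(b2t)), state.eps)
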