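"""PPO exploration of degenerate near-optimal sequences on a Potts landscape.

The best single sequence from the combinatorial solver is only one of many
possible good binders: the score landscape is typically degenerate, with
alternate sequences scoring within a few kcal/mol of the optimum.  A
proximal-policy-optimization (PPO) agent is trained on the landscape and
then used to harvest these alternates.

The policy network embeds each residue's amino acid, runs the embedded
sequence through a gated recurrent unit (GRU), and maps the final hidden
state through a linear layer + softmax to a joint distribution over
(position, amino-acid) substitution actions.  A value head sharing the
recurrent trunk provides the critic for generalized advantage estimation.
The per-step reward is the *decrease* in Potts score, so the policy drifts
toward low-scoring (high-affinity) sequences; a sequence visited during
rollout counts as an alternate solution when its score lies within a fixed
window (default 5 score units) of the best known score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .potts import Alphabet, PottsModel, potts_score, validate_sequence

__all__ = [
    "TrainConfig",
    "ActionSpec",
    "PolicyParameters",
    "AlternateSet",
    "policy_distribution",
    "apply_action",
    "step_reward",
    "ppo_train",
    "collect_alternates",
]


@dataclass
class TrainConfig:
    clip_epsilon: float = 0.2
    kl_limit: float = 0.05
    learning_rate: float = 3e-4
    horizon: int = 50
    updates: int = 60
    batch_size: int = 16
    discount: float = 0.99
    gae_lambda: float = 0.95
    epochs_per_update: int = 4
    entropy_coef: float = 0.01
    value_coef: float = 0.5
    d_emb: int = 16
    d_h: int = 64
    seed: int = 0
    reward_sign_flip: bool = True   # reward = -(delta score); see methods note

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_epsilon < 1.0):
            raise ValueError("clip_epsilon must be in (0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class ActionSpec:
    position: int
    amino_acid: str


class PolicyParameters:
    """Embedding + GRU + linear policy/value heads as named Tensors."""

    def __init__(self, n: int, alphabet: Alphabet, d_emb: int = 16,
                 d_h: int = 64, seed: int = 0):
        self.n = n
        self.alphabet = alphabet
        self.d_emb = d_emb
        self.d_h = d_h
        A = len(alphabet)
        rng = np.random.default_rng(seed)

        def init(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "emb": init(A, d_emb, scale=0.1),
            # GRU gates: update z, reset r, candidate h
            "W_z": init(d_emb, d_h), "U_z": init(d_h, d_h), "b_z": Tensor(np.zeros(d_h), True),
            "W_r": init(d_emb, d_h), "U_r": init(d_h, d_h), "b_r": Tensor(np.zeros(d_h), True),
            "W_h": init(d_emb, d_h), "U_h": init(d_h, d_h), "b_h": Tensor(np.zeros(d_h), True),
            "W_out": init(d_h, n * A, scale=0.01), "b_out": Tensor(np.zeros(n * A), True),
            "W_v": init(d_h, 1, scale=0.01), "b_v": Tensor(np.zeros(1), True),
        }

    @property
    def n_actions(self) -> int:
        return self.n * len(self.alphabet)

    def forward(self, states: np.ndarray) -> tuple[Tensor, Tensor]:
        """Batch forward pass.

        ``states``: (B, n) integer matrix of amino-acid indices.
        Returns (log_probs (B, n*A), values (B, 1)).
        """
        p = self.params
        B, n = states.shape
        h = Tensor(np.zeros((B, self.d_h)))
        for t in range(n):
            x = p["emb"].gather_rows(states[:, t])
            z = (x @ p["W_z"] + h @ p["U_z"] + p["b_z"]).sigmoid()
            r = (x @ p["W_r"] + h @ p["U_r"] + p["b_r"]).sigmoid()
            h_tilde = (x @ p["W_h"] + (r * h) @ p["U_h"] + p["b_h"]).tanh()
            h = (1.0 - z) * h + z * h_tilde
        logits = h @ p["W_out"] + p["b_out"]
        log_probs = logits.log_softmax()
        values = h @ p["W_v"] + p["b_v"]
        return log_probs, values

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "n": self.n, "letters": self.alphabet.letters,
            "d_emb": self.d_emb, "d_h": self.d_h,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "PolicyParameters":
        blob = json.loads(Path(path).read_text())
        obj = cls(blob["n"], Alphabet(blob["letters"]), blob["d_emb"], blob["d_h"])
        for k, v in blob["params"].items():
            obj.params[k].data = np.array(v, dtype=float)
        return obj


def policy_distribution(params: PolicyParameters, state: str) -> np.ndarray:
    """Action probabilities (length n*|alphabet|) for one sequence state."""
    validate_sequence(state, params.alphabet, params.n)
    states = params.alphabet.encode(state)[None, :]
    log_probs, _ = params.forward(states)
    return np.exp(log_probs.data[0])


def apply_action(state: str, action: ActionSpec, alphabet: Alphabet) -> str:
    """Substitute one position's amino acid (identity if same letter)."""
    if not (0 <= action.position < len(state)):
        raise IndexError(f"position {action.position} out of range for n={len(state)}")
    if action.amino_acid not in alphabet:
        raise ValueError(f"letter {action.amino_acid!r} not in alphabet")
    return state[:action.position] + action.amino_acid + state[action.position + 1:]


def step_reward(model: PottsModel, s_t: str, s_t1: str,
                sign_flip: bool = True) -> float:
    """Reward for the transition s_t -> s_t1.

    The raw score change is score(s_t1) - score(s_t); with ``sign_flip``
    (default) the reward is its negative, so score *decreases* are rewarded
    and the policy seeks high-affinity sequences.
    """
    delta = potts_score(model, s_t1) - potts_score(model, s_t)
    return -delta if sign_flip else delta


def _action_to_spec(action: int, n: int, alphabet: Alphabet) -> ActionSpec:
    A = len(alphabet)
    return ActionSpec(position=action // A, amino_acid=alphabet.letters[action % A])


def _rollout(params: PolicyParameters, model: PottsModel, seed_sequence: str,
             config: TrainConfig, rng: np.random.Generator):
    """Collect one batch of episodes, all starting at ``seed_sequence``."""
    alphabet = params.alphabet
    B, T = config.batch_size, config.horizon
    n = params.n
    states_buf = np.zeros((T, B, n), dtype=np.intp)
    actions_buf = np.zeros((T, B), dtype=np.intp)
    logp_buf = np.zeros((T, B))
    value_buf = np.zeros((T, B))
    reward_buf = np.zeros((T, B))
    visited: set[str] = set()

    seqs = [seed_sequence] * B
    scores = np.array([potts_score(model, s) for s in seqs])
    for t in range(T):
        states = np.stack([alphabet.encode(s) for s in seqs])
        log_probs, values = params.forward(states)
        probs = np.exp(log_probs.data)
        actions = np.array([rng.choice(params.n_actions, p=probs[b])
                            for b in range(B)])
        states_buf[t] = states
        actions_buf[t] = actions
        logp_buf[t] = log_probs.data[np.arange(B), actions]
        value_buf[t] = values.data[:, 0]
        new_seqs, new_scores = [], []
        for b in range(B):
            spec = _action_to_spec(int(actions[b]), n, alphabet)
            s1 = apply_action(seqs[b], spec, alphabet)
            sc1 = potts_score(model, s1)
            delta = sc1 - scores[b]
            reward_buf[t, b] = -delta if config.reward_sign_flip else delta
            new_seqs.append(s1)
            new_scores.append(sc1)
            visited.add(s1)
        seqs = new_seqs
        scores = np.array(new_scores)
    mean_final = float(scores.mean())
    return states_buf, actions_buf, logp_buf, value_buf, reward_buf, visited, mean_final


def _gae(rewards: np.ndarray, values: np.ndarray, discount: float,
         lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation over (T, B) arrays (episodes end at T)."""
    T, B = rewards.shape
    adv = np.zeros((T, B))
    last = np.zeros(B)
    for t in range(T - 1, -1, -1):
        next_value = values[t + 1] if t + 1 < T else np.zeros(B)
        delta = rewards[t] + discount * next_value - values[t]
        last = delta + discount * lam * last
        adv[t] = last
    returns = adv + values
    return adv, returns


def ppo_train(model: PottsModel, seed_sequence: str,
              config: TrainConfig | None = None) -> tuple[PolicyParameters, list[dict]]:
    """Train a PPO policy on the Potts landscape starting from the solver's
    best sequence.  Deterministic given ``config.seed``.

    Returns the trained parameters and a training log (one dict per update
    with mean_reward, mean_final_score, approx_kl, loss, skipped).
    """
    config = config or TrainConfig()
    validate_sequence(seed_sequence, model.alphabet, model.n)
    rng = np.random.default_rng(config.seed)
    params = PolicyParameters(model.n, model.alphabet, config.d_emb,
                              config.d_h, seed=config.seed)
    opt = Adam(params.params, lr=config.learning_rate)
    log: list[dict] = []

    for update in range(config.updates):
        (states_buf, actions_buf, logp_old, value_buf, rewards,
         _visited, mean_final) = _rollout(params, model, seed_sequence, config, rng)
        adv, returns = _gae(rewards, value_buf, config.discount, config.gae_lambda)
        adv_flat = adv.reshape(-1)
        adv_flat = (adv_flat - adv_flat.mean()) / (adv_flat.std() + 1e-8)
        states_flat = states_buf.reshape(-1, model.n)
        actions_flat = actions_buf.reshape(-1)
        logp_old_flat = logp_old.reshape(-1)
        returns_flat = returns.reshape(-1)

        approx_kl = 0.0
        loss_val = float("nan")
        skipped = False
        for _ in range(config.epochs_per_update):
            log_probs, values = params.forward(states_flat)
            logp_new = log_probs.take_along_last(actions_flat)
            approx_kl = float(np.mean(logp_old_flat - logp_new.data))
            if approx_kl > config.kl_limit:
                skipped = True
                break
            ratio = (logp_new - Tensor(logp_old_flat)).exp()
            adv_t = Tensor(adv_flat)
            surrogate = (ratio * adv_t).minimum(
                ratio.clip(1.0 - config.clip_epsilon, 1.0 + config.clip_epsilon) * adv_t)
            policy_loss = -surrogate.mean()
            value_loss = ((values.reshape(-1) - Tensor(returns_flat)) ** 2).mean()
            entropy = -(log_probs * log_probs.exp()).sum() * (1.0 / len(states_flat))
            loss = policy_loss + config.value_coef * value_loss - config.entropy_coef * entropy
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite PPO loss at update {update}: "
                    f"policy={policy_loss.data}, value={value_loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_val = float(loss.data)
        log.append({
            "update": update,
            "mean_reward": float(rewards.mean()),
            "mean_final_score": mean_final,
            "approx_kl": approx_kl,
            "loss": loss_val,
            "skipped": skipped,
        })
    return params, log


@dataclass
class AlternateSet:
    """Near-optimal sequences within ``window`` of the best known score."""

    seed_sequence: str
    best_score: float
    window: float = 5.0
    members: list = field(default_factory=list)   # (sequence, score) tuples

    def __post_init__(self) -> None:
        seen = set()
        cleaned = []
        for seq, score in self.members:
            if seq == self.seed_sequence or seq in seen:
                continue
            if score <= self.best_score + self.window + 1e-9:
                seen.add(seq)
                cleaned.append((seq, score))
        self.members = cleaned

    def __len__(self) -> int:
        return len(self.members)


def collect_alternates(params: PolicyParameters, model: PottsModel,
                       best_score: float, window: float = 5.0,
                       budget: int = 100_000, seed: int = 0,
                       start_sequence: str | None = None,
                       horizon: int = 50) -> AlternateSet:
    """Roll the trained policy and harvest every visited sequence whose
    score is within ``window`` of ``best_score`` (seed sequence excluded).

    ``budget`` caps the total number of policy steps across rollouts.
    """
    alphabet = model.alphabet
    if start_sequence is None:
        raise ValueError("start_sequence is required (typically the solver optimum)")
    validate_sequence(start_sequence, alphabet, model.n)
    rng = np.random.default_rng(seed)
    members: dict[str, float] = {}
    scored: set[str] = set()
    steps = 0
    B = 32   # parallel rollouts per policy forward
    while steps < budget:
        seqs = [start_sequence] * B
        for _ in range(horizon):
            if steps >= budget:
                break
            states = np.stack([alphabet.encode(s) for s in seqs])
            log_probs, _ = params.forward(states)
            probs = np.exp(log_probs.data)
            for b in range(B):
                if steps >= budget:
                    break
                action = int(rng.choice(params.n_actions, p=probs[b]))
                seqs[b] = apply_action(seqs[b], _action_to_spec(action, model.n, alphabet),
                                       alphabet)
                steps += 1
                s = seqs[b]
                if s not in scored and s != start_sequence:
                    scored.add(s)
                    score = potts_score(model, s)
                    if score <= best_score + window + 1e-9:
                        members[s] = score
    return AlternateSet(seed_sequence=start_sequence, best_score=best_score,
                        window=window,
                        members=sorted(members.items(), key=lambda kv: kv[1]))
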