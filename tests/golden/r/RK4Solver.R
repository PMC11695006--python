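# RK4Solver.R - fixed-step fourth-order Runge-Kutta
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

TimeGrid <- function(t0, t1, step) {
  n_full <- floor((t1 - t0) / step + 1e-9)
  times <- t0 + (0:n_full) * step
  last <- length(times)
  if (abs(times[last] - t1) <= 1e-9 * step) {
    times[last] <- t1
  } else if (times[last] < t1) {
    times <- base::c(times, t1)
  }
  times
}

RK4Step <- function(f, t, y, h) {
  k1 <- f(t, y)
  k2 <- f(t + 0.5 * h, y + 0.5 * h * k1)
  k3 <- f(t + 0.5 * h, y + 0.5 * h * k2)
  k4 <- f(t + h, y + h * k3)
  y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
}

Integrate <- function(f, times, y0) {
  states <- matrix(0.0, nrow = length(times), ncol = length(y0))
  states[1, ] <- y0
  y <- y0
  for (i in 2:length(times)) {
    y <- RK4Step(f, times[i - 1], y, times[i] - times[i - 1])
    states[i, ] <- y
  }
  states
}

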