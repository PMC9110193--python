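"""Line-by-line transcription of the published FSIM reference code
(Zhang et al., "FSIM: A Feature Similarity Index for Image Quality
Assessment", IEEE TIP 2011; original MATLAB implementation) for use as an
independent oracle in tests.  Deliberately kept in the original's
structure and naming; do not refactor against ctpdeconv.metrics.
"""

import numpy as np


def lowpassfilter(sze, cutoff, n):
    rows, cols = sze
    if cols % 2:
        xrange = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xrange = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yrange = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yrange = np.arange(-rows / 2, rows / 2) / rows
    x, y = np.meshgrid(xrange, yrange)
    radius = np.sqrt(x**2 + y**2)
    f = np.fft.ifftshift(1.0 / (1.0 + (radius / cutoff) ** (2 * n)))
    return f


def phasecong2(im):
    nscale = 4
    norient = 4
    minWaveLength = 6
    mult = 2
    sigmaOnf = 0.55
    dThetaOnSigma = 1.2
    k = 2.0
    epsilon = 0.0001
    thetaSigma = np.pi / norient / dThetaOnSigma

    rows, cols = im.shape
    imagefft = np.fft.fft2(im)
    zero = np.zeros((rows, cols))
    EO = {}
    ifftFilterArray = [None] * nscale

    if cols % 2:
        xrange = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xrange = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yrange = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yrange = np.arange(-rows / 2, rows / 2) / rows
    x, y = np.meshgrid(xrange, yrange)
    radius = np.sqrt(x**2 + y**2)
    theta = np.arctan2(-y, x)
    radius = np.fft.ifftshift(radius)
    theta = np.fft.ifftshift(theta)
    radius[0, 0] = 1.0
    sintheta = np.sin(theta)
    costheta = np.cos(theta)

    lp = lowpassfilter((rows, cols), 0.45, 15)
    logGabor = []
    for s in range(nscale):
        wavelength = minWaveLength * mult**s
        fo = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / fo) ** 2) / (2 * np.log(sigmaOnf) ** 2))
        lg = lg * lp
        lg[0, 0] = 0.0
        logGabor.append(lg)

    EnergyAll = zero.copy()
    AnAll = zero.copy()
    for o in range(norient):
        angl = o * np.pi / norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * thetaSigma**2))
        sumE_ThisOrient = zero.copy()
        sumO_ThisOrient = zero.copy()
        sumAn_ThisOrient = zero.copy()
        Energy = zero.copy()
        EM_n = None
        for s in range(nscale):
            filt = logGabor[s] * spread
            ifftFilt = np.real(np.fft.ifft2(filt)) * np.sqrt(rows * cols)
            ifftFilterArray[s] = ifftFilt
            EO[(s, o)] = np.fft.ifft2(imagefft * filt)
            An = np.abs(EO[(s, o)])
            sumAn_ThisOrient = sumAn_ThisOrient + An
            sumE_ThisOrient = sumE_ThisOrient + np.real(EO[(s, o)])
            sumO_ThisOrient = sumO_ThisOrient + np.imag(EO[(s, o)])
            if s == 0:
                EM_n = np.sum(filt**2)
        XEnergy = np.sqrt(sumE_ThisOrient**2 + sumO_ThisOrient**2) + epsilon
        MeanE = sumE_ThisOrient / XEnergy
        MeanO = sumO_ThisOrient / XEnergy
        for s in range(nscale):
            E = np.real(EO[(s, o)])
            O = np.imag(EO[(s, o)])
            Energy = Energy + E * MeanE + O * MeanO - np.abs(E * MeanO - O * MeanE)
        medianE2n = np.median(np.abs(EO[(0, o)]) ** 2)
        meanE2n = medianE2n / np.log(2)
        noisePower = meanE2n / EM_n
        EstSumAn2 = zero.copy()
        for s in range(nscale):
            EstSumAn2 = EstSumAn2 + ifftFilterArray[s] ** 2
        EstSumAiAj = zero.copy()
        for si in range(nscale - 1):
            for sj in range(si + 1, nscale):
                EstSumAiAj = EstSumAiAj + ifftFilterArray[si] * ifftFilterArray[sj]
        sumEstSumAn2 = np.sum(EstSumAn2)
        sumEstSumAiAj = np.sum(EstSumAiAj)
        EstNoiseEnergy2 = 2 * noisePower * sumEstSumAn2 + 4 * noisePower * sumEstSumAiAj
        tau = np.sqrt(EstNoiseEnergy2 / 2)
        EstNoiseEnergy = tau * np.sqrt(np.pi / 2)
        EstNoiseEnergySigma = np.sqrt((2 - np.pi / 2) * tau**2)
        T = EstNoiseEnergy + k * EstNoiseEnergySigma
        T = T / 1.7
        Energy = np.maximum(Energy - T, zero)
        EnergyAll = EnergyAll + Energy
        AnAll = AnAll + sumAn_ThisOrient
    ResultPC = EnergyAll / AnAll
    return ResultPC


def fsim_reference(imageRef, imageDis):
    """FSIM between two grayscale images on the 0-255 intensity scale."""
    from scipy.signal import convolve2d

    I1 = np.asarray(imageRef, dtype=float)
    I2 = np.asarray(imageDis, dtype=float)
    rows, cols = I1.shape
    minDimension = min(rows, cols)
    F = max(1, int(round(minDimension / 256)))
    aveKernel = np.ones((F, F)) / (F * F)
    aveI1 = convolve2d(I1, aveKernel, mode="same")
    aveI2 = convolve2d(I2, aveKernel, mode="same")
    I1 = aveI1[0:rows:F, 0:cols:F]
    I2 = aveI2[0:rows:F, 0:cols:F]

    PC1 = phasecong2(I1)
    PC2 = phasecong2(I2)

    dx = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0
    dy = np.array([[3, 10, 3], [0, 0, 0], [-3, -10, -3]]) / 16.0
    IxI1 = convolve2d(I1, dx, mode="same")
    IyI1 = convolve2d(I1, dy, mode="same")
    gradientMap1 = np.sqrt(IxI1**2 + IyI1**2)
    IxI2 = convolve2d(I2, dx, mode="same")
    IyI2 = convolve2d(I2, dy, mode="same")
    gradientMap2 = np.sqrt(IxI2**2 + IyI2**2)

    T1 = 0.85
    T2 = 160.0
    PCSimMatrix = (2 * PC1 * PC2 + T1) / (PC1**2 + PC2**2 + T1)
    gradientSimMatrix = (2 * gradientMap1 * gradientMap2 + T2) / (
        gradientMap1**2 + gradientMap2**2 + T2
    )
    PCm = np.maximum(PC1, PC2)
    SimMatrix = gradientSimMatrix * PCSimMatrix * PCm
    return float(np.sum(SimMatrix) / np.sum(PCm))
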