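# angiopd parameter configuration
organism = human
delta_D = 8.64e-07  # cm^2/day
delta_T = 8.64e-07  # cm^2/day
delta_E = 8.64e-07  # cm^2/day
delta_C = 8.64e-07  # cm^2/day
delta_I12 = 0.0605  # cm^2/day
delta_I2 = 0.0958  # cm^2/day
delta_Tb = 0.0852  # cm^2/day
delta_W = 0.8  # cm^2/day
delta_G = 0.0864  # cm^2/day
delta_A = 0.0473  # cm^2/day
delta_B = 0.047  # cm^2/day
sigma_T = 1.0  # 1/cm
sigma_E = 1.0  # 1/cm
sigma_W = 1.0  # 1/cm
chi_G = 10.0  # cm^5/(g day)
lam_DC = 7.5  # 1/day
lam_T1I12 = 11.65  # 1/day
lam_T1I2 = 0.25  # 1/day
lam_T8I12 = 10.38  # 1/day
lam_T8I2 = 0.25  # 1/day
lam_TrTb = 0.415  # 1/day
lam_TrG = 0.083  # 1/day
lam_E = 20800000.0  # cm^3/(g day)
lam_CW = 1.76  # 1/day
lam_I12D = 2.21e-06  # 1/day
lam_I2T1 = 2.82e-08  # 1/day
lam_TbC = 3.27e-10  # 1/day
lam_TbTr = 5.57e-09  # 1/day
lam_WE = 0.07  # 1/day
lam_GW = 2.21e-06  # 1/day
d_D = 0.1  # 1/day
d_T1 = 0.197  # 1/day
d_T8 = 0.18  # 1/day
d_Tr = 0.2  # 1/day
d_E = 0.69  # 1/day
d_C = 0.17  # 1/day
d_I12 = 1.38  # 1/day
d_I2 = 2.376  # 1/day
d_Tb = 499.066  # 1/day
d_W = 1.04  # 1/day
d_G = 12.6  # 1/day
d_A = 0.34  # 1/day
d_B = 0.17  # 1/day
eta_1 = 30.19  # cm^3/(g day)
eta_8 = 60.375  # cm^3/(g day)
mu_PA = 43300000.0  # cm^3/(g day)
mu_AP = 43300000.0  # cm^3/(g day)
mu_GB = 131000000.0  # cm^3/(g day)
mu_BG = 21900000.0  # cm^3/(g day)
K_D = 0.0004  # g/cm^3
K_T1 = 0.002  # g/cm^3
K_T8 = 0.001  # g/cm^3
K_Tr = 0.0005  # g/cm^3
K_E = 0.0025  # g/cm^3
K_C = 0.4  # g/cm^3
K_I12 = 8e-10  # g/cm^3
K_I2 = 2.37e-11  # g/cm^3
K_Tb = 2.68e-13  # g/cm^3
K_W = 0.000169  # g/cm^3
K_G = 7e-08  # g/cm^3
K_TTr = 0.0005  # g/cm^3
K_DG = 2.8e-07  # g/cm^3
K_TG = 2.8e-07  # g/cm^3
Kp_TQ = 1.68e-18  # g^2/cm^6
K_PB = 1e-09  # g/cm^3
K_B = 1e-09  # g/cm^3
D_0 = 2e-05  # g/cm^3
T_10 = 0.0004  # g/cm^3
T_80 = 0.0002  # g/cm^3
E_M = 0.005  # g/cm^3
C_M = 0.8  # g/cm^3
T1_hat = 0.004  # g/cm^3
T8_hat = 0.002  # g/cm^3
E_hat = 0.005  # g/cm^3
G_0 = 3.65e-10  # g/cm^3
W_star = 0.000169  # g/cm^3
W_0 = 0.000465  # g/cm^3
W_blood = 0.000169  # g/cm^3
rho_P = 2.49e-07  # -
rho_L = 5.22e-07  # -
eps_T = 0.8  # -
eps_C = 0.01  # -
eps_G = 1430000.0  # cm^3/g
gamma_A = 0.0  # g/(cm^3 day)
gamma_B = 0.0  # g/(cm^3 day)
theta = 0.4064  # g/cm^3
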