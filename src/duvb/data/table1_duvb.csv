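city,annual_mean,annual_sd,m1_mean,m1_sd,m2_mean,m2_sd,m3_mean,m3_sd,m4_mean,m4_sd,m5_mean,m5_sd,m6_mean,m6_sd,m7_mean,m7_sd,m8_mean,m8_sd,m9_mean,m9_sd,m10_mean,m10_sd,m11_mean,m11_sd,m12_mean,m12_sd
Nicosia,5.57,3.55,1.23,0.16,2.23,0.42,4.07,0.56,6.24,0.81,8.31,0.81,10.33,0.57,11.06,0.27,9.51,0.63,6.78,0.90,3.84,0.79,1.92,0.37,1.13,0.12
Valletta,5.02,3.38,1.03,0.11,1.88,0.42,3.52,0.72,5.68,0.69,7.96,0.54,9.45,0.69,10.35,0.34,8.78,0.71,5.75,0.89,3.17,0.66,1.51,0.32,0.92,0.08
Athens,4.78,3.30,0.87,0.12,1.65,0.36,3.24,0.60,5.36,0.72,7.44,0.51,9.08,0.64,10.02,0.28,8.55,0.58,5.70,0.95,3.01,0.74,1.40,0.36,0.77,0.11
Lisbon,4.51,3.06,0.89,0.14,1.70,0.34,3.28,0.53,5.07,0.71,7.21,0.55,8.64,0.53,9.19,0.26,7.86,0.64,5.27,0.75,2.81,0.75,1.26,0.27,0.78,0.06
Ankara,4.66,3.45,0.71,0.12,1.39,0.27,2.79,0.58,4.99,0.75,7.21,0.72,9.05,0.72,10.42,0.33,8.76,0.68,5.68,0.98,2.83,0.73,1.23,0.32,0.62,0.08
Madrid,4.48,3.20,0.76,0.14,1.51,0.33,3.07,0.55,4.96,0.65,7.18,0.56,8.92,0.67,9.57,0.28,7.94,0.67,5.16,0.83,2.69,0.75,1.12,0.27,0.67,0.06
Tirana,4.01,3.06,0.57,0.10,1.12,0.27,2.38,0.61,4.31,0.67,6.35,0.71,8.16,0.75,9.04,0.44,7.54,0.66,4.60,0.87,2.33,0.51,0.98,0.29,0.50,0.05
Rome,3.97,3.01,0.56,0.09,1.17,0.27,2.45,0.61,4.36,0.54,6.44,0.68,8.20,0.70,8.82,0.38,7.28,0.68,4.47,0.76,2.27,0.52,0.91,0.24,0.49,0.04
Skopje,3.84,2.93,0.57,0.12,1.22,0.26,2.24,0.53,4.12,0.68,6.07,0.64,7.81,0.69,8.61,0.47,7.27,0.61,4.41,0.88,2.21,0.54,0.90,0.29,0.44,0.06
Podgorica,3.90,3.04,0.50,0.10,1.01,0.25,2.26,0.62,4.31,0.69,6.31,0.78,8.14,0.74,8.79,0.40,7.35,0.64,4.45,0.84,2.19,0.52,0.86,0.26,0.43,0.04
AndorralaVella,3.69,2.94,0.41,0.04,0.84,0.24,1.98,0.51,3.70,0.59,5.90,0.67,7.73,0.88,8.57,0.38,7.04,0.65,4.45,0.75,2.31,0.62,0.77,0.25,0.37,0.03
Pristina,3.81,2.94,0.49,0.12,1.18,0.26,2.26,0.57,4.21,0.72,6.12,0.66,7.87,0.59,8.53,0.44,7.19,0.65,4.33,0.91,2.11,0.54,0.83,0.27,0.38,0.06
Sofia,3.75,2.86,0.55,0.11,1.16,0.25,2.24,0.53,4.11,0.67,5.96,0.61,7.55,0.68,8.40,0.40,7.15,0.62,4.33,0.90,2.09,0.51,0.84,0.28,0.42,0.04
Monaco,3.79,2.93,0.49,0.09,1.05,0.28,2.33,0.52,4.23,0.66,6.32,0.65,8.03,0.61,8.42,0.32,6.90,0.62,4.26,0.71,2.08,0.58,0.79,0.21,0.41,0.04
Sarajevo,3.41,2.68,0.43,0.10,0.99,0.25,2.07,0.57,3.75,0.62,5.47,0.62,7.21,0.75,7.71,0.56,6.47,0.66,3.82,0.85,1.85,0.48,0.70,0.23,0.34,0.04
SanMarino,3.55,2.85,0.41,0.06,0.88,0.24,2.08,0.57,3.93,0.58,5.90,0.76,7.68,0.72,8.19,0.45,6.56,0.62,3.96,0.75,1.82,0.46,0.67,0.21,0.35,0.04
Bucharest,3.54,2.82,0.42,0.08,0.96,0.23,2.04,0.50,4.00,0.71,5.95,0.64,7.47,0.57,7.98,0.32,6.71,0.68,4.03,0.84,1.80,0.50,0.64,0.22,0.32,0.03
Belgrade,3.39,2.72,0.34,0.08,0.90,0.25,1.97,0.54,3.86,0.72,5.66,0.71,7.28,0.65,7.70,0.50,6.31,0.64,3.77,0.84,1.76,0.49,0.64,0.21,0.27,0.04
Zagreb,3.19,2.64,0.31,0.06,0.72,0.22,1.80,0.50,3.66,0.65,5.41,0.75,7.14,0.57,7.35,0.51,5.94,0.65,3.48,0.67,1.58,0.46,0.51,0.16,0.24,0.03
Ljubljana,3.11,2.61,0.29,0.06,0.69,0.23,1.74,0.45,3.53,0.59,5.24,0.76,6.99,0.64,7.30,0.47,5.81,0.67,3.42,0.67,1.48,0.42,0.47,0.14,0.23,0.02
Bern,3.11,2.49,0.34,0.08,0.83,0.27,1.94,0.48,3.64,0.62,5.22,0.85,6.87,0.70,6.97,0.49,5.49,0.54,3.53,0.68,1.54,0.44,0.51,0.16,0.27,0.03
Chisinau,3.16,2.66,0.30,0.06,0.72,0.20,1.69,0.46,3.48,0.72,5.47,0.69,7.06,0.52,7.30,0.32,6.05,0.66,3.49,0.74,1.48,0.49,0.45,0.18,0.21,0.02
Vaduz,3.04,2.45,0.30,0.07,0.77,0.25,1.81,0.49,3.59,0.62,5.13,0.76,6.76,0.66,6.76,0.51,5.41,0.60,3.47,0.68,1.55,0.42,0.51,0.16,0.25,0.02
Budapest,3.09,2.59,0.25,0.06,0.64,0.20,1.69,0.47,3.63,0.68,5.34,0.68,6.92,0.49,7.09,0.49,5.78,0.59,3.39,0.68,1.47,0.46,0.47,0.19,0.19,0.03
Bratislava,2.97,2.53,0.22,0.06,0.64,0.22,1.60,0.44,3.57,0.70,5.20,0.67,6.81,0.41,6.90,0.43,5.42,0.63,3.26,0.64,1.32,0.44,0.40,0.15,0.17,0.02
Vienna,2.91,2.45,0.25,0.06,0.67,0.21,1.58,0.44,3.53,0.71,5.04,0.65,6.59,0.47,6.72,0.40,5.30,0.61,3.18,0.64,1.29,0.44,0.39,0.14,0.17,0.02
Paris,2.70,2.29,0.20,0.05,0.53,0.17,1.47,0.40,3.26,0.59,4.83,0.66,6.21,0.45,6.21,0.39,4.80,0.56,3.06,0.65,1.20,0.37,0.35,0.12,0.16,0.02
Luxembourg,2.63,2.28,0.17,0.04,0.48,0.17,1.39,0.41,3.18,0.62,4.79,0.68,6.18,0.43,6.11,0.42,4.64,0.55,2.94,0.64,1.09,0.33,0.30,0.10,0.13,0.01
Prague,2.64,2.30,0.19,0.06,0.53,0.18,1.36,0.41,3.18,0.70,4.76,0.68,6.23,0.38,6.16,0.39,4.79,0.59,2.86,0.61,1.08,0.36,0.29,0.10,0.15,0.02
Kiev,2.72,2.45,0.18,0.05,0.47,0.16,1.29,0.43,3.02,0.67,4.94,0.75,6.53,0.44,6.47,0.28,5.24,0.69,2.85,0.67,1.08,0.41,0.27,0.11,0.13,0.02
Brussels,2.43,2.12,0.15,0.04,0.42,0.14,1.26,0.39,2.95,0.60,4.54,0.62,5.75,0.43,5.63,0.40,4.24,0.54,2.69,0.58,1.00,0.31,0.27,0.10,0.12,0.02
London,2.32,2.05,0.14,0.04,0.40,0.14,1.19,0.33,2.77,0.54,4.31,0.54,5.56,0.38,5.49,0.39,4.06,0.60,2.54,0.59,0.91,0.29,0.26,0.09,0.11,0.02
Warsaw,2.43,2.21,0.14,0.04,0.40,0.13,1.14,0.39,2.82,0.61,4.46,0.67,5.97,0.35,5.81,0.34,4.55,0.60,2.55,0.57,0.91,0.33,0.22,0.09,0.10,0.01
Amsterdam,2.29,2.06,0.12,0.03,0.36,0.13,1.16,0.39,2.79,0.59,4.41,0.55,5.56,0.36,5.37,0.45,4.05,0.59,2.43,0.57,0.86,0.30,0.22,0.08,0.09,0.01
Berlin,2.32,2.11,0.11,0.04,0.38,0.15,1.09,0.35,2.77,0.67,4.36,0.67,5.68,0.29,5.48,0.35,4.25,0.58,2.44,0.59,0.84,0.30,0.21,0.08,0.08,0.01
Dublin,2.08,1.88,0.11,0.03,0.34,0.13,1.08,0.35,2.51,0.48,4.05,0.65,5.14,0.28,4.89,0.42,3.51,0.44,2.18,0.51,0.75,0.27,0.21,0.08,0.08,0.01
Minsk,2.28,2.12,0.10,0.03,0.36,0.14,1.14,0.39,2.59,0.52,4.28,0.71,5.68,0.41,5.54,0.27,4.30,0.67,2.24,0.60,0.72,0.28,0.16,0.08,0.07,0.01
Vilnius,2.16,2.03,0.09,0.03,0.31,0.12,1.04,0.36,2.46,0.56,4.12,0.69,5.44,0.28,5.27,0.26,4.04,0.65,2.12,0.58,0.66,0.26,0.14,0.07,0.06,0.01
Copenhagen,2.05,1.97,0.07,0.02,0.24,0.10,0.89,0.33,2.42,0.57,4.05,0.57,5.26,0.22,5.07,0.39,3.71,0.63,2.02,0.57,0.63,0.25,0.13,0.05,0.05,0.00
Moscow,2.10,2.04,0.08,0.03,0.29,0.11,0.91,0.33,2.25,0.51,4.13,0.58,5.40,0.42,5.28,0.28,4.08,0.66,1.90,0.49,0.58,0.26,0.12,0.05,0.06,0.00
Riga,1.98,1.93,0.06,0.02,0.25,0.11,0.90,0.33,2.21,0.56,3.86,0.59,5.12,0.28,5.04,0.34,3.66,0.65,1.82,0.52,0.53,0.24,0.10,0.05,0.04,0.00
Stockholm,1.76,1.80,0.03,0.01,0.15,0.07,0.66,0.28,1.93,0.51,3.49,0.53,4.77,0.28,4.69,0.34,3.20,0.58,1.54,0.46,0.40,0.19,0.07,0.03,0.02,0.00
Tallinn,1.76,1.82,0.04,0.01,0.15,0.07,0.66,0.27,1.90,0.50,3.59,0.59,4.79,0.25,4.71,0.40,3.26,0.66,1.48,0.46,0.39,0.19,0.07,0.03,0.02,0.00
Oslo,1.65,1.70,0.03,0.01,0.15,0.07,0.64,0.27,1.81,0.46,3.26,0.55,4.57,0.25,4.43,0.35,2.97,0.53,1.42,0.49,0.36,0.17,0.06,0.03,0.02,0.00
Helsinki,1.75,1.84,0.03,0.01,0.14,0.07,0.61,0.27,1.81,0.48,3.55,0.57,4.79,0.30,4.81,0.40,3.26,0.71,1.44,0.46,0.36,0.18,0.06,0.03,0.02,0.00
Reykjavik,1.16,1.29,0.01,0.01,0.06,0.03,0.32,0.15,1.15,0.34,2.46,0.36,3.41,0.23,3.28,0.29,2.15,0.45,0.82,0.28,0.20,0.10,0.03,0.01,0.01,0.00
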