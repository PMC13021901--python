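T_K,P_bar,y,co2_density
313,95,0.75,576.5599
313,110,1.06,682.684
313,130,1.24,743.5779
313,145,1.51,772.9667
313,160,1.79,795.9429
313,180,2.12,820.6486
313,200,2.46,841.0035
313,250,3.01,880.7093
318,95,0.68,424.3987
318,110,1.12,600.9256
318,130,1.64,693.3373
318,145,2.25,732.1035
318,160,2.76,760.79
318,180,3.08,790.1662
318,200,3.6,813.7248
318,250,5.05,858.2483
333,95,1.1,262.686
333,110,1.47,362.7499
333,130,2.36,507.4301
333,145,3.83,584.1816
333,160,5.14,637.4255
333,180,7.16,687.4706
333,200,9.02,724.1375
333,250,12.03,787.3101
345,95,2.15,222.2849
345,110,3.04,286.4008
345,130,4.09,390.1502
345,145,6.27,467.5024
345,160,8.18,532.2831
345,180,10.61,597.9683
345,200,12.27,646.4997
345,250,15.7,727.3968
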