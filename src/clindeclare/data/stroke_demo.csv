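Case_ID,Event_ID,Activity,Actor,Timestamp
1,423,Admit,Pete,2019/1/13 10:16
1,424,CT examination,Sue,2019/1/13 10:26
1,425,Blood sugar test,Mike,2019/1/13 10:19
1,426,Intravenous thrombolysis,Sara,2019/1/13 10:56
1,427,Statins drugs,Mike,2019/1/13 11:38
1,428,Discharge,John,2019/1/20 12:18
2,483,Admit,Pete,2019/3/25 15:16
2,485,Blood sugar test,Mike,2019/3/25 15:26
2,487,MRI examination,Sue,2019/3/25 15:45
2,488,Have a fever,Sara,2019/3/26 08:30
2,489,Anticoagulant drugs,Sean,2019/3/26 11:16
2,490,Antiplatelet drugs,Mike,2019/3/27 10:22
2,493,Insulin injection,Ellen,2019/3/27 19:48
3,641,Admit,Pete,2019/4/5 22:34
3,643,Intravenous thrombolysis,Sara,2019/4/5 23:46
3,644,Hypertensive,Mike,2019/4/6 09:10
3,645,Anticoagulant drugs,Sean,2019/4/6 13:10
3,648,Statins drugs,Sean,2019/4/7 18:35
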