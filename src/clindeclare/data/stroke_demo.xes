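<?xml version='1.0' encoding='UTF-8'?>
<log xes.version="1.0" xes.features="nested-attributes">
  <trace>
    <string key="concept:name" value="1"/>
    <event>
      <string key="concept:name" value="Admit"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-13T10:16:00"/>
      <string key="identity:id" value="423"/>
      <string key="executor" value="Pete">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Blood sugar test"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-13T10:19:00"/>
      <string key="identity:id" value="425"/>
      <string key="executor" value="Mike">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="CT examination"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-13T10:26:00"/>
      <string key="identity:id" value="424"/>
      <string key="executor" value="Sue">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Intravenous thrombolysis"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-13T10:56:00"/>
      <string key="identity:id" value="426"/>
      <string key="executor" value="Sara">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Statins drugs"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-13T11:38:00"/>
      <string key="identity:id" value="427"/>
      <string key="executor" value="Mike">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Discharge"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-01-20T12:18:00"/>
      <string key="identity:id" value="428"/>
      <string key="executor" value="John">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
  </trace>
  <trace>
    <string key="concept:name" value="2"/>
    <event>
      <string key="concept:name" value="Admit"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-25T15:16:00"/>
      <string key="identity:id" value="483"/>
      <string key="executor" value="Pete">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Blood sugar test"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-25T15:26:00"/>
      <string key="identity:id" value="485"/>
      <string key="executor" value="Mike">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="MRI examination"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-25T15:45:00"/>
      <string key="identity:id" value="487"/>
      <string key="executor" value="Sue">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Have a fever"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-26T08:30:00"/>
      <string key="identity:id" value="488"/>
      <string key="executor" value="Sara">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Anticoagulant drugs"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-26T11:16:00"/>
      <string key="identity:id" value="489"/>
      <string key="executor" value="Sean">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Antiplatelet drugs"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-27T10:22:00"/>
      <string key="identity:id" value="490"/>
      <string key="executor" value="Mike">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Insulin injection"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-03-27T19:48:00"/>
      <string key="identity:id" value="493"/>
      <string key="executor" value="Ellen">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
  </trace>
  <trace>
    <string key="concept:name" value="3"/>
    <event>
      <string key="concept:name" value="Admit"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-04-05T22:34:00"/>
      <string key="identity:id" value="641"/>
      <string key="executor" value="Pete">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Intravenous thrombolysis"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-04-05T23:46:00"/>
      <string key="identity:id" value="643"/>
      <string key="executor" value="Sara">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Hypertensive"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-04-06T09:10:00"/>
      <string key="identity:id" value="644"/>
      <string key="executor" value="Mike">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Anticoagulant drugs"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-04-06T13:10:00"/>
      <string key="identity:id" value="645"/>
      <string key="executor" value="Sean">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
    <event>
      <string key="concept:name" value="Statins drugs"/>
      <string key="lifecycle:transition" value="complete"/>
      <date key="time:timestamp" value="2019-04-07T18:35:00"/>
      <string key="identity:id" value="648"/>
      <string key="executor" value="Sean">
        <string key="clin:kind" value="action"/>
      </string>
    </event>
  </trace>
</log>
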